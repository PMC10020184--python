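import numpy as np
import pandas as pd
import pytest

from pupdyad import PipelineConfig, TrackingTable


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_track(
    config: PipelineConfig,
    pup_xy: np.ndarray,
    nest_xy: tuple[float, float],
    pup_likelihood: np.ndarray | None = None,
    dam_xy: np.ndarray | None = None,
    dam_likelihood: np.ndarray | None = None,
    fps: float | None = None,
) -> TrackingTable:
    """Build a minimal tracking table: one pup part, one dam part, one nest.

    ``pup_xy`` is (n, 2) in px; likelihoods default to 1.
    """
    pup_xy = np.asarray(pup_xy, dtype=float)
    n = len(pup_xy)
    if pup_likelihood is None:
        pup_likelihood = np.ones(n)
    if dam_xy is None:
        dam_xy = np.tile(np.asarray(nest_xy, dtype=float), (n, 1))
    if dam_likelihood is None:
        dam_likelihood = np.ones(n)
    pup_part = config.body_parts["pup"][0]
    dam_part = config.body_parts["dam"][0]
    nest_part = config.body_parts["nest"][0]
    cols = {
        (pup_part, "x"): pup_xy[:, 0],
        (pup_part, "y"): pup_xy[:, 1],
        (pup_part, "likelihood"): np.asarray(pup_likelihood, dtype=float),
        (dam_part, "x"): np.asarray(dam_xy, dtype=float)[:, 0],
        (dam_part, "y"): np.asarray(dam_xy, dtype=float)[:, 1],
        (dam_part, "likelihood"): np.asarray(dam_likelihood, dtype=float),
        (nest_part, "x"): np.full(n, nest_xy[0], dtype=float),
        (nest_part, "y"): np.full(n, nest_xy[1], dtype=float),
        (nest_part, "likelihood"): np.ones(n),
    }
    data = pd.DataFrame(cols)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    data.index = pd.RangeIndex(n, name="frame")
    return TrackingTable(
        data=data,
        fps=fps or config.video_fps,
        px_per_mm=config.px_per_mm,
        roles={"dam": (dam_part,), "pup": (pup_part,), "nest": (nest_part,)},
    )
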