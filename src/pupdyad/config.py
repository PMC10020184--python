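"""Pipeline configuration.

All tunable constants of the retrieval/USV pipeline live here so that every
stage reads the same values: camera and audio-trim frame rates, the trial
window, the trajectory quality-control thresholds, and the validation and
statistics knobs.  The configuration can be loaded from / saved to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULT_BODY_PARTS"]

#: Default body-part -> role map.  The tracked keypoint list is a property of
#: the upstream pose-estimation model and is therefore configurable; these
#: names are only the package's defaults for synthetic data.
DEFAULT_BODY_PARTS: dict[str, tuple[str, ...]] = {
    "dam": ("dam_nose", "dam_centroid", "dam_tailbase"),
    "pup": ("pup_nose", "pup_centroid", "pup_tailbase"),
    "nest": ("nest",),
}


@dataclass
class PipelineConfig:
    """Constants shared by every pipeline stage.

    Durations and distances are strictly positive; probabilities lie in
    [0, 1]; ``loess_span`` lies in (0, 1].  Violations raise ``ValueError``
    at construction.
    """

    video_fps: float = 30.0              # camera frame rate (frames/s)
    audio_trim_fps: float = 25.0         # audio trim granularity (frames/s)
    trial_duration: float = 100.0        # trial window after the beep (s)
    start_clamp_distance: float = 85.0   # minimum plausible start distance (mm)
    rolling_median_window: int = 90      # trailing window for start clamp (frames)
    min_mean_pup_likelihood: float = 0.01  # frame discarded below this mean
    keypoint_p_cutoff: float = 0.10      # per-keypoint cutoff for centroids
    loess_span: float = 0.25             # local-regression span (fraction)
    smooth_outlier_distance: float = 15.0  # residual cutoff (mm)
    px_per_mm: float = 2.27              # camera scale (px/mm)
    nest_entry_radius: float = 30.0      # "entered the nest" radius (mm)
    flag_threshold: float = 30.0         # manual-vs-auto flag cutoff (s)
    usv_window_short: float = 10.0       # early-call window (s)
    poor_retriever_cutoff: float = 0.5   # dam exclusion threshold (fraction)
    eval_grid_step: float = 0.001        # segment-evaluation grid (s)
    self_return_proximity: float = 50.0  # dam-pup distance for self-return (mm)
    self_return_lookback: float = 3.0    # window before nest entry (s)
    rng_seed: int = 0
    body_parts: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BODY_PARTS.items()}
    )

    def __post_init__(self) -> None:
        positive = {
            "video_fps": self.video_fps,
            "audio_trim_fps": self.audio_trim_fps,
            "trial_duration": self.trial_duration,
            "start_clamp_distance": self.start_clamp_distance,
            "rolling_median_window": self.rolling_median_window,
            "smooth_outlier_distance": self.smooth_outlier_distance,
            "px_per_mm": self.px_per_mm,
            "nest_entry_radius": self.nest_entry_radius,
            "flag_threshold": self.flag_threshold,
            "usv_window_short": self.usv_window_short,
            "eval_grid_step": self.eval_grid_step,
            "self_return_proximity": self.self_return_proximity,
            "self_return_lookback": self.self_return_lookback,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name, value in (
            ("min_mean_pup_likelihood", self.min_mean_pup_likelihood),
            ("keypoint_p_cutoff", self.keypoint_p_cutoff),
            ("poor_retriever_cutoff", self.poor_retriever_cutoff),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError(f"loess_span must lie in (0, 1], got {self.loess_span!r}")
        self.body_parts = {role: tuple(parts) for role, parts in self.body_parts.items()}
        for role in ("dam", "pup", "nest"):
            if role not in self.body_parts:
                raise ValueError(f"body_parts must define role {role!r}")
        if len(self.body_parts["nest"]) != 1:
            raise ValueError("the nest role must map to exactly one body part")

    @property
    def alignment_uncertainty(self) -> float:
        """One audio trim frame, in seconds (40 ms at the 25 fps default)."""
        return 1.0 / self.audio_trim_fps

    def part_role(self, part: str) -> str:
        for role, parts in self.body_parts.items():
            if part in parts:
                return role
        raise KeyError(f"body part {part!r} is not mapped to any role")

    # -- YAML round trip -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "body_parts" in raw:
            raw["body_parts"] = {k: tuple(v) for k, v in raw["body_parts"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["body_parts"] = {k: list(v) for k, v in data["body_parts"].items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
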