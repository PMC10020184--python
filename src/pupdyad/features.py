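"""Per-trial vocalization features on the synchronized segment table.

All features use the half-open convention uniformly: a call belongs to a
window when its *start* falls inside it, so a call straddling the retrieval
instant counts as emitted before retrieval.

Rate is defined as the number of calls before retrieval divided by the
retrieval time (calls/s); for non-retrieved pups the retrieval time is the
censoring time (100 s), so all calls count.  Durations are stored in
seconds and reported in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import USVSegmentTable

__all__ = [
    "TrialFeatures",
    "count_before",
    "usv_rate",
    "mean_duration",
    "first_latency_and_window_counts",
    "compute_trial_features",
]


@dataclass
class TrialFeatures:
    """Derived per-trial outputs."""

    n_usv_total: int
    n_usv_before_retrieval: int
    usv_rate: float          # calls/s; NaN when undefined (retrieval at t=0)
    mean_usv_duration: float  # ms; NaN when no call before retrieval
    first_usv_latency: float  # s; NaN when the trial has no call
    n_usv_first_10s: int
    retrieval_time: float
    success: int
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        out = {
            "n_usv_total": self.n_usv_total,
            "n_usv_before_retrieval": self.n_usv_before_retrieval,
            "usv_rate": self.usv_rate,
            "mean_usv_duration": self.mean_usv_duration,
            "first_usv_latency": self.first_usv_latency,
            "n_usv_first_10s": self.n_usv_first_10s,
            "retrieval_time": self.retrieval_time,
            "success": self.success,
            "flags": ";".join(sorted(self.flags)),
        }
        return out


def count_before(segments: USVSegmentTable, retrieval_time: float) -> int:
    """Number of calls starting before the retrieval instant."""
    return int((segments.starts < retrieval_time).sum())


def usv_rate(n_before: int, retrieval_time: float) -> float:
    """Call rate = calls before retrieval / retrieval time (calls/s).

    Undefined (NaN) when retrieval_time is 0.
    """
    if retrieval_time < 0:
        raise ValueError(f"retrieval_time must be non-negative, got {retrieval_time}")
    if retrieval_time == 0:
        return math.nan
    return n_before / retrieval_time


def mean_duration(segments: USVSegmentTable, retrieval_time: float) -> float:
    """Mean duration (ms) of calls starting before retrieval; NaN if none."""
    before = segments.starts < retrieval_time
    if not before.any():
        return math.nan
    return float(np.mean(segments.durations[before]) * 1000.0)


def first_latency_and_window_counts(
    segments: USVSegmentTable, config: PipelineConfig
) -> tuple[float, int]:
    """Latency to the first call (s; NaN if silent) and the early-window count.

    The early window is [0, usv_window_short), 10 s by default, half-open:
    a call starting exactly at 10 s is outside.
    """
    if len(segments) == 0:
        return math.nan, 0
    starts = segments.starts
    return float(starts.min()), int((starts < config.usv_window_short).sum())


def compute_trial_features(
    segments: USVSegmentTable,
    retrieval_time: float,
    success: int,
    config: PipelineConfig,
    flags: set[str] | frozenset[str] = frozenset(),
) -> TrialFeatures:
    """Assemble the full per-trial feature record.

    ``segments`` must already be on the trial clock, hand-censored and
    clipped.  A silent trial yields a complete, valid record (zero counts,
    missing duration/latency).
    """
    n_total = len(segments)
    n_before = count_before(segments, retrieval_time)
    rate = usv_rate(n_before, retrieval_time)
    out_flags = set(flags)
    if math.isnan(rate):
        out_flags.add("zero_retrieval_time")
    latency, n_first10 = first_latency_and_window_counts(segments, config)
    return TrialFeatures(
        n_usv_total=n_total,
        n_usv_before_retrieval=n_before,
        usv_rate=rate,
        mean_usv_duration=mean_duration(segments, retrieval_time),
        first_usv_latency=latency,
        n_usv_first_10s=n_first10,
        retrieval_time=retrieval_time,
        success=success,
        flags=out_flags,
    )


def features_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-trial feature dicts (plus identifiers) into one table."""
    return pd.DataFrame(rows)
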