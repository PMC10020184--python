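"""Trajectory quality control and retrieval-time estimation.

From raw keypoints to a per-trial retrieval estimate, in a fixed order:

1. ``compute_distance_series`` — pup-to-nest distance per frame; the pup
   centroid uses only keypoints above the per-keypoint likelihood cutoff
   (0.10).
2. ``apply_start_clamp`` — pups start far (> 85 mm) from the nest; early
   frames where a 90-frame trailing rolling median of the distance has not
   yet exceeded 85 mm are tracking artefacts and are clamped to 85 mm.
3. ``filter_low_probability`` — frames whose mean pup likelihood over all
   pup keypoints is below 0.01 are discarded.
4. ``smooth_and_reject`` — a degree-2 loess (span 0.25) approximates the
   distance trace; observations deviating more than 15 mm from the fit are
   set to missing.
5. ``estimate_retrieval`` — retrieval time is the first remaining frame
   with distance at or below the nest-entry radius; trials with no such
   frame are censored at the trial end.

Each stage only adds missingness or clamps values; none invents data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import TrackingTable
from .smoothing import loess_fit, trailing_median

__all__ = [
    "DistanceSeries",
    "RetrievalEstimate",
    "compute_distance_series",
    "apply_start_clamp",
    "filter_low_probability",
    "smooth_and_reject",
    "estimate_retrieval",
    "flag_self_return",
    "estimate_trial",
    "QualityWarning",
]

#: per-frame quality-mask codes
MASK_KEPT = "kept"
MASK_LOW_LIKELIHOOD = "low_likelihood"
MASK_SMOOTH_OUTLIER = "smooth_outlier"
MASK_CLAMPED = "clamped"


class QualityWarning(UserWarning):
    """Raised (as a warning) when a trial's tracking quality is degraded."""


@dataclass
class DistanceSeries:
    """Pup-to-nest distance per frame with a per-frame quality mask.

    ``d`` is in millimetres, NaN where missing; ``t`` in seconds is strictly
    increasing; ``mask`` assigns exactly one code per frame.
    """

    t: np.ndarray
    d: np.ndarray
    mask: np.ndarray
    flags: set[str]

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.d) == len(self.mask)):
            raise ValueError("t, d and mask must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "d_mm": self.d, "mask": self.mask})


@dataclass
class RetrievalEstimate:
    """Automated retrieval estimate for one trial.

    success = 0, censored = True and retrieval_time = trial_duration are
    equivalent statements for a pup never reaching the nest zone.
    """

    retrieval_time: float
    success: int
    censored: bool
    self_return_flag: bool = False
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.success == 0) != self.censored:
            raise ValueError("success=0 and censored must agree")


def _pup_centroid(track: TrackingTable, config: PipelineConfig) -> np.ndarray:
    """(n, 2) pup centroid using keypoints with likelihood >= the cutoff.

    Frames where no pup keypoint passes the cutoff are NaN.
    """
    parts = track.roles["pup"]
    if not parts:
        raise ValueError("tracking table has no pup body parts")
    xy = np.stack([track.xy(p) for p in parts], axis=1)          # (n, P, 2)
    lk = track.likelihood(parts)                                  # (n, P)
    use = lk >= config.keypoint_p_cutoff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centroid = np.nanmean(
            np.where(use[:, :, None], xy, np.nan), axis=1
        )
    centroid[~use.any(axis=1)] = np.nan
    return centroid


def compute_distance_series(
    track: TrackingTable, config: PipelineConfig
) -> DistanceSeries:
    """Per-frame pup-to-nest distance in millimetres.

    The pup position is the mean of pup keypoints whose likelihood passes
    the per-keypoint cutoff; the nest position is the (median) nest
    keypoint.  Distances are Euclidean in pixels divided by the camera
    scale.  Raises if no frame is usable at all.
    """
    if not track.roles["nest"]:
        raise ValueError("tracking table has no nest point")
    centroid = _pup_centroid(track, config)
    nest_xy = track.xy(track.roles["nest"][0])
    # the nest is static; use its median position to resist tracking noise
    nest = np.nanmedian(nest_xy, axis=0)
    d_px = np.hypot(centroid[:, 0] - nest[0], centroid[:, 1] - nest[1])
    d = d_px / track.px_per_mm
    if np.all(np.isnan(d)):
        raise ValueError("no frame has a usable pup position in the whole trial")
    mask = np.where(np.isnan(d), MASK_LOW_LIKELIHOOD, MASK_KEPT)
    return DistanceSeries(t=track.times(), d=d, mask=mask, flags=set())


def apply_start_clamp(ds: DistanceSeries, config: PipelineConfig) -> DistanceSeries:
    """Clamp implausible early distances to the known minimum start distance.

    Pups start more than ``start_clamp_distance`` (85 mm) from the nest, so
    early frames where the trailing rolling median (90 frames) of the
    distance has not yet exceeded that bound reflect tracking errors; their
    distance is set to exactly the bound and marked ``clamped``.  If the
    rolling median never exceeds the bound nothing is clamped and a warning
    flag is raised.
    """
    if not ds.present.any():
        raise ValueError("distance series has no present values")
    med = trailing_median(ds.d, config.rolling_median_window)
    above = med > config.start_clamp_distance
    flags = set(ds.flags)
    if not above.any():
        flags.add("rolling_median_never_above_start_distance")
        warnings.warn(
            "rolling median never exceeded the start-clamp distance; "
            "start clamp not applied",
            QualityWarning,
            stacklevel=2,
        )
        return replace(ds, flags=flags)
    first = int(np.argmax(above))
    if first == 0:
        return replace(ds, flags=flags)
    d = ds.d.copy()
    mask = ds.mask.copy()
    d[:first] = config.start_clamp_distance
    mask[:first] = MASK_CLAMPED
    return replace(ds, d=d, mask=mask, flags=flags)


def filter_low_probability(
    ds: DistanceSeries, track: TrackingTable, config: PipelineConfig
) -> DistanceSeries:
    """Discard frames whose mean pup likelihood is below the floor (0.01).

    The mean is over *all* pup keypoints (not only those passing the
    centroid cutoff); such frames are considered unreliable outright.
    """
    lk = track.likelihood(track.roles["pup"])
    low = lk.mean(axis=1) < config.min_mean_pup_likelihood
    d = ds.d.copy()
    mask = ds.mask.copy()
    d[low] = np.nan
    mask[low] = MASK_LOW_LIKELIHOOD
    return replace(ds, d=d, mask=mask)


def smooth_and_reject(ds: DistanceSeries, config: PipelineConfig) -> DistanceSeries:
    """Loess-smooth the distance trace and reject gross outliers.

    A degree-2 tricube loess with span ``loess_span`` is fitted once to the
    present (pre-rejection) points with time as the predictor; present
    observations deviating more than ``smooth_outlier_distance`` (15 mm)
    from the fit become missing (``smooth_outlier``).  With too few points
    to fit, the series passes through unchanged with a quality flag.
    """
    present = ds.present
    n_present = int(present.sum())
    n_min = max(10, int(np.ceil(config.loess_span * n_present)))
    if n_present < n_min:
        flags = set(ds.flags)
        flags.add("too_few_points_for_smoothing")
        warnings.warn(
            f"only {n_present} present points; smoothing skipped",
            QualityWarning,
            stacklevel=2,
        )
        return replace(ds, flags=flags)
    fitted = loess_fit(ds.t[present], ds.d[present], span=config.loess_span)
    resid = np.abs(ds.d[present] - fitted)
    reject = resid > config.smooth_outlier_distance
    d = ds.d.copy()
    mask = ds.mask.copy()
    idx = np.flatnonzero(present)[reject]
    d[idx] = np.nan
    mask[idx] = MASK_SMOOTH_OUTLIER
    return replace(ds, d=d, mask=mask)


def estimate_retrieval(ds: DistanceSeries, config: PipelineConfig) -> RetrievalEstimate:
    """Retrieval time = time of the first present frame inside the nest zone.

    If the cleaned distance never reaches ``nest_entry_radius`` the trial is
    censored: success = 0 and retrieval_time = trial_duration.  An
    all-missing series yields a censored estimate with a quality flag,
    never an exception.
    """
    flags = set(ds.flags)
    if not ds.present.any():
        flags.add("no_usable_frames")
        warnings.warn("no usable frames; censored estimate", QualityWarning, stacklevel=2)
        return RetrievalEstimate(
            retrieval_time=config.trial_duration,
            success=0,
            censored=True,
            flags=frozenset(flags),
        )
    inside = ds.present & (ds.d <= config.nest_entry_radius)
    if not inside.any():
        return RetrievalEstimate(
            retrieval_time=config.trial_duration,
            success=0,
            censored=True,
            flags=frozenset(flags),
        )
    first = int(np.argmax(inside))
    return RetrievalEstimate(
        retrieval_time=float(ds.t[first]),
        success=1,
        censored=False,
        flags=frozenset(flags),
    )


def flag_self_return(
    track: TrackingTable, est: RetrievalEstimate, config: PipelineConfig
) -> RetrievalEstimate:
    """Flag trials where the pup reached the nest without the dam.

    If during the look-back window (3 s) before nest entry the dam centroid
    never comes within the proximity radius (50 mm) of the pup, the pup
    walked itself back; such trials are excluded from dyadic statistics.
    Heuristic thresholds — the study identified self-returns by eye.
    """
    if est.success != 1:
        return est
    dam_parts = track.roles["dam"]
    if not dam_parts:
        flags = set(est.flags)
        flags.add("self_return_indeterminate")
        warnings.warn("no dam track; self-return flag indeterminate",
                      QualityWarning, stacklevel=2)
        return replace(est, flags=frozenset(flags))
    t = track.times()
    window = (t >= est.retrieval_time - config.self_return_lookback) & (
        t <= est.retrieval_time
    )
    dam_xy = np.stack([track.xy(p) for p in dam_parts], axis=1)
    dam_lk = track.likelihood(dam_parts)
    use = dam_lk >= config.keypoint_p_cutoff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dam_c = np.nanmean(np.where(use[:, :, None], dam_xy, np.nan), axis=1)
    dam_c[~use.any(axis=1)] = np.nan
    pup_c = _pup_centroid(track, config)
    prox = (
        np.hypot(dam_c[:, 0] - pup_c[:, 0], dam_c[:, 1] - pup_c[:, 1])
        / track.px_per_mm
    )
    prox_w = prox[window]
    valid = ~np.isnan(prox_w)
    if not valid.any():
        flags = set(est.flags)
        flags.add("self_return_indeterminate")
        warnings.warn("dam or pup untracked before entry; self-return flag "
                      "indeterminate", QualityWarning, stacklevel=2)
        return replace(est, flags=frozenset(flags))
    flagged = bool(np.nanmin(prox_w) > config.self_return_proximity)
    return replace(est, self_return_flag=flagged)


def estimate_trial(
    track: TrackingTable, config: PipelineConfig
) -> tuple[RetrievalEstimate, DistanceSeries]:
    """Run the full QC chain and estimator on one trial-windowed track."""
    try:
        ds = compute_distance_series(track, config)
    except ValueError:
        warnings.warn("no usable pup positions in trial; censored estimate",
                      QualityWarning, stacklevel=2)
        t = track.times()
        ds = DistanceSeries(
            t=t,
            d=np.full(len(t), np.nan),
            mask=np.full(len(t), MASK_LOW_LIKELIHOOD),
            flags={"no_usable_frames"},
        )
        est = RetrievalEstimate(
            retrieval_time=config.trial_duration, success=0, censored=True,
            flags=frozenset(ds.flags),
        )
        return est, ds
    ds = apply_start_clamp(ds, config)
    ds = filter_low_probability(ds, track, config)
    ds = smooth_and_reject(ds, config)
    est = estimate_retrieval(ds, config)
    est = flag_self_return(track, est, config)
    return est, ds
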