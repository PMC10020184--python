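"""Synthetic pup-retrieval cohorts with known ground truth.

The generator emulates the study design end to end: 29 dams tested on
postnatal days 5, 7, 9, 11 and 13, six trials per dam on PND5 and four on
the other days (22 per dam); a pup placed in the far corner (> 85 mm from
the nest, ~310 mm at the default cage geometry); 30 fps video keypoints
with per-frame confidence and dropout; a pup call point process whose rate
peaks at PND7-9; and a retrieval hazard coupled (negatively by default) to
the pup's call rate, with a positive within-day maternal-learning effect.

Two resolutions are provided:

* :func:`simulate_features` draws only trial-level outcomes (fast; used
  for statistical calibration at many replicates);
* :func:`simulate_trial` / :func:`simulate_cohort` additionally emit full
  keypoint trajectories, call segment tables on the raw audio clock, and
  per-trial metadata with imperfect "manual" scores, in the exact file
  dialects the pipeline reads.

Retrieval is drawn as ``t_min + Exponential(h)`` with a fixed offset
``hazard_delay`` and hazard ``h = base_hazard * exp(beta_usv_rate * rate +
beta_trial * (trial - 1))``, censored at the trial end.  The fixed offset
keeps the proportional-hazards structure exact while preventing retrieval
before the experimenter's hand has left the cage.

Every trial owns an RNG stream derived from (seed, dam, day, trial), so
cohorts are reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import (
    TrackingTable,
    TrialRecord,
    USVSegmentTable,
    write_tracking_table,
    write_trial_metadata,
    write_usv_segments,
)

__all__ = ["SimParams", "SyntheticTrial", "simulate_features", "simulate_trial",
           "simulate_cohort", "iter_trials"]

_DAY_RATES = {5: 1.8, 7: 2.8, 9: 2.6, 11: 2.0, 13: 1.4}


@dataclass
class SimParams:
    """Study-design and noise parameters of the synthetic cohort."""

    n_dams: int = 29
    pups_per_litter: int = 6
    days: tuple[int, ...] = (5, 7, 9, 11, 13)
    trials_pnd5: int = 6
    trials_other: int = 4
    conditions: tuple[str, ...] = ("thiq_high", "thiq_low", "vehicle")

    # retrieval hazard model
    base_hazard: float = 0.04            # 1/s
    beta_usv_rate: float = math.log(0.58)   # log-hazard per call/s
    beta_trial: float = math.log(1.19)      # log-hazard per trial
    hazard_delay: float = 2.0            # fixed pre-hazard offset (s)
    coupling: str = "rate_to_hazard"     # or "hazard_to_rate"
    reverse_coupling: float = -0.5       # log-rate per (T/100 - 0.5), reverse mode

    # call point process
    usv_base_rate: dict[int, float] = field(default_factory=lambda: dict(_DAY_RATES))
    rate_shape: float = 4.0              # gamma shape of the per-trial latent rate
    usv_duration_mean: float = 35.0      # ms (female)
    usv_duration_sigma: float = 0.35     # lognormal shape
    sex_duration_effect: float = -8.0    # ms added for males

    # trajectory & tracking noise
    start_corner: tuple[float, float] = (310.0, 250.0)   # mm
    nest_position: tuple[float, float] = (60.0, 60.0)    # mm
    start_jitter: float = 8.0            # mm around the corner
    carry_duration: tuple[float, float] = (2.0, 4.0)     # s
    track_noise_sd: float = 2.0          # mm per keypoint
    dropout_prob: float = 0.05           # per frame per keypoint
    likelihood_visible: tuple[float, float] = (10.0, 0.5)   # Beta params
    likelihood_dropout: tuple[float, float] = (0.4, 8.0)

    # manual scoring noise and rare events
    manual_error_sd: float = 3.0         # s
    manual_disagree_prob: float = 0.04
    self_return_prob: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dams < 0:
            raise ValueError("n_dams must be non-negative")
        for p in (self.dropout_prob, self.manual_disagree_prob, self.self_return_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.base_hazard <= 0 or self.rate_shape <= 0:
            raise ValueError("base_hazard and rate_shape must be positive")
        if self.coupling not in ("rate_to_hazard", "hazard_to_rate"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        missing = set(self.days) - set(self.usv_base_rate)
        if missing:
            raise ValueError(f"usv_base_rate lacks day(s) {sorted(missing)}")

    def trials_on(self, pnd: int) -> int:
        return self.trials_pnd5 if pnd == 5 else self.trials_other

    @property
    def occlusion_prob(self) -> float:
        """Hand/dam occlusion probability, tied to the dropout level."""
        return min(1.0, 12.0 * self.dropout_prob)


@dataclass
class SyntheticTrial:
    """One emitted trial plus its ground truth."""

    track: TrackingTable          # raw video clock (frames from recording start)
    segments: USVSegmentTable     # raw audio clock
    record: TrialRecord
    truth: dict


def _trial_rng(params: SimParams, dam_idx: int, pnd: int, seq: int) -> np.random.Generator:
    return np.random.default_rng([params.seed % (2**31), dam_idx, pnd, seq])


def _trial_design(params: SimParams) -> list[tuple[int, int, int, str, str]]:
    """(dam_idx, pnd, seq, sex, condition) for every trial in the design."""
    out = []
    for dam in range(params.n_dams):
        condition = params.conditions[dam % len(params.conditions)]
        for pnd in params.days:
            for seq in range(1, params.trials_on(pnd) + 1):
                # pup sex counterbalanced within dam and day
                sex = "male" if (seq + dam) % 2 == 0 else "female"
                out.append((dam, pnd, seq, sex, condition))
    return out


def _draw_outcome(
    params: SimParams, config: PipelineConfig, pnd: int, seq: int, sex: str,
    rng: np.random.Generator,
) -> dict:
    """Ground-truth outcome and call events for one trial."""
    duration = config.trial_duration
    base = params.usv_base_rate[pnd]
    lam = rng.gamma(params.rate_shape, base / params.rate_shape)
    hand_exit = rng.uniform(1.0, 1.8)

    if params.coupling == "rate_to_hazard":
        h = params.base_hazard * math.exp(
            params.beta_usv_rate * lam + params.beta_trial * (seq - 1)
        )
        t_exp = params.hazard_delay + rng.exponential(1.0 / h)
    else:
        h = params.base_hazard * math.exp(params.beta_trial * (seq - 1))
        t_exp = params.hazard_delay + rng.exponential(1.0 / h)
        lam *= math.exp(
            params.reverse_coupling * (min(t_exp, duration) / duration - 0.5)
        )

    self_return = rng.random() < params.self_return_prob
    if self_return:
        retrieval_time = rng.uniform(0.3 * duration, 0.9 * duration)
        success = 1
    elif t_exp < duration:
        retrieval_time, success = t_exp, 1
    else:
        retrieval_time, success = duration, 0

    # call events: homogeneous point process at the latent rate, from shortly
    # after placement to the trial end
    t0 = 0.3
    n_events = rng.poisson(lam * (duration - t0))
    times = np.sort(rng.uniform(t0, duration, n_events))
    mean_ms = max(params.usv_duration_mean
                  + (params.sex_duration_effect if sex == "male" else 0.0), 5.0)
    mu = math.log(mean_ms) - params.usv_duration_sigma**2 / 2
    dur_s = np.exp(rng.normal(mu, params.usv_duration_sigma, n_events)) / 1000.0
    if n_events > 1:  # keep segments disjoint
        gap = np.diff(times)
        dur_s[:-1] = np.minimum(dur_s[:-1], np.maximum(gap - 1e-3, 1e-3))
    stops = np.minimum(times + dur_s, duration)

    # manual score: ground truth plus timing error, occasional disagreement
    if self_return:
        manual_success, manual_time = 0, duration    # scored as "dam did not retrieve"
    elif rng.random() < params.manual_disagree_prob:
        manual_success = 1 - success
        manual_time = (duration if manual_success == 0
                       else rng.uniform(0.8 * duration, duration - 0.5))
    else:
        manual_success = success
        if success:
            manual_time = float(
                np.clip(retrieval_time + rng.normal(0.0, params.manual_error_sd),
                        hand_exit + 0.1, duration - 1e-3)
            )
        else:
            manual_time = duration

    return {
        "true_rate": lam,
        "retrieval_time": float(retrieval_time),
        "success": success,
        "self_return": self_return,
        "hand_exit_time": float(hand_exit),
        "event_times": times,
        "event_stops": stops,
        "manual_retrieval_time": float(manual_time),
        "manual_success": manual_success,
    }


def _event_features(
    truth: dict, config: PipelineConfig
) -> dict:
    """Measured call features implied by the ground-truth events."""
    starts = truth["event_times"]
    stops = truth["event_stops"]
    keep = starts >= truth["hand_exit_time"]   # hand-interval calls are censored
    starts, stops = starts[keep], stops[keep]
    rt = truth["retrieval_time"]
    before = starts < rt
    n_before = int(before.sum())
    return {
        "n_usv_total": int(len(starts)),
        "n_usv_before_retrieval": n_before,
        "usv_rate": n_before / rt if rt > 0 else math.nan,
        "mean_usv_duration": (
            float(np.mean((stops[before] - starts[before])) * 1000.0)
            if n_before else math.nan
        ),
        "first_usv_latency": float(starts.min()) if len(starts) else math.nan,
        "n_usv_first_10s": int((starts < config.usv_window_short).sum()),
    }


def simulate_features(
    params: SimParams, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Trial-level cohort draw: ground truth and measured features, no video.

    One row per trial of the full design.  ``usv_rate`` etc. are the
    features an ideal pipeline would measure from the emitted events (with
    hand-interval censoring); ``true_rate`` is the latent rate that drives
    the hazard.
    """
    config = config or PipelineConfig()
    rows = []
    for dam, pnd, seq, sex, condition in _trial_design(params):
        rng = _trial_rng(params, dam, pnd, seq)
        truth = _draw_outcome(params, config, pnd, seq, sex, rng)
        row = {
            "dam_id": f"dam{dam:03d}",
            "pup_sex": sex,
            "pnd": pnd,
            "maternal_trial_seq": seq,
            "condition": condition,
            "true_rate": truth["true_rate"],
            "retrieval_time": truth["retrieval_time"],
            "success": truth["success"],
            "self_return": truth["self_return"],
            "hand_exit_time": truth["hand_exit_time"],
            "manual_retrieval_time": truth["manual_retrieval_time"],
            "manual_success": truth["manual_success"],
        }
        row.update(_event_features(truth, config))
        rows.append(row)
    cols = list(rows[0]) if rows else [
        "dam_id", "pup_sex", "pnd", "maternal_trial_seq", "condition",
        "true_rate", "retrieval_time", "success", "self_return",
        "hand_exit_time", "manual_retrieval_time", "manual_success",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# full-resolution trials
# ---------------------------------------------------------------------------

def _keypoint_block(
    rng: np.random.Generator,
    params: SimParams,
    config: PipelineConfig,
    path_mm: np.ndarray,
    offsets: np.ndarray,
    occluded: np.ndarray,
) -> dict[str, np.ndarray]:
    """Emit x/y/likelihood arrays for one animal's keypoints."""
    n = len(path_mm)
    out = {}
    a_vis, b_vis = params.likelihood_visible
    a_drop, b_drop = params.likelihood_dropout
    for j in range(len(offsets)):
        pos = path_mm + offsets[j]
        if params.track_noise_sd > 0:
            pos = pos + rng.normal(0.0, params.track_noise_sd, (n, 2))
        dropped = occluded | (rng.random(n) < params.dropout_prob)
        lk = np.where(
            dropped,
            rng.beta(a_drop, b_drop, n),
            rng.beta(a_vis, b_vis, n),
        )
        out[j] = (pos * config.px_per_mm, lk)
    return out


def simulate_trial(
    params: SimParams,
    config: PipelineConfig,
    dam_idx: int,
    pnd: int,
    seq: int,
    sex: str | None = None,
    condition: str | None = None,
) -> SyntheticTrial:
    """Emit one full trial: keypoint track, call segments, metadata, truth."""
    if sex is None:
        sex = "male" if (seq + dam_idx) % 2 == 0 else "female"
    if condition is None:
        condition = params.conditions[dam_idx % len(params.conditions)]
    rng = _trial_rng(params, dam_idx, pnd, seq)
    truth = _draw_outcome(params, config, pnd, seq, sex, rng)
    duration = config.trial_duration
    fps = config.video_fps

    beep_frame = int(rng.integers(30, 150))
    audio_offset = float(rng.uniform(1.0, 5.0))
    n_trial_frames = int(round(duration * fps))
    n_frames = beep_frame + n_trial_frames
    t = (np.arange(n_frames) - beep_frame) / fps      # trial clock per frame

    nest = np.asarray(params.nest_position)
    corner = np.asarray(params.start_corner) + rng.uniform(
        -params.start_jitter, params.start_jitter, 2
    )
    d_start = float(np.hypot(*(corner - nest)))
    radius = config.nest_entry_radius

    # --- pup path -----------------------------------------------------------
    pup = np.tile(corner, (n_frames, 1))
    entry = truth["retrieval_time"]
    if truth["success"]:
        if truth["self_return"]:
            move_dur = rng.uniform(10.0, 30.0)
        else:
            move_dur = float(rng.uniform(*params.carry_duration))
        # the pup crosses the nest radius exactly at the ground-truth entry
        # time; the move covers the full corner->nest distance
        frac_at_entry = 1.0 - radius / d_start
        total = move_dur / frac_at_entry
        move_start = entry - move_dur
        if move_start < truth["hand_exit_time"] + 0.2:
            move_start = truth["hand_exit_time"] + 0.2
            total = (entry - move_start) / frac_at_entry
        frac = np.clip((t - move_start) / total, 0.0, 1.0)
        pup = corner + np.outer(frac, nest - corner)
        # settle just off the nest centre once deposited
        settled = frac >= 1.0
        pup[settled] = nest + rng.normal(0.0, 2.0, 2)
    # --- dam path ------------------------------------------------------------
    dam = np.tile(nest, (n_frames, 1))
    wander = 25.0 * np.column_stack(
        [np.sin(0.23 * t + rng.uniform(0, 6.28)), np.cos(0.31 * t + rng.uniform(0, 6.28))]
    )
    dam = dam + wander
    if truth["success"] and not truth["self_return"]:
        move_end = entry + radius / d_start * total + 1.0 / fps
        approach_start = move_start - rng.uniform(1.0, 3.0)
        to_pup = np.clip((t - approach_start) / (move_start - approach_start), 0, 1)
        seg = (t >= approach_start) & (t < move_start)
        dam[seg] = dam[seg] + to_pup[seg, None] * (corner - dam[seg])
        carrying = (t >= move_start) & (t <= move_end)
        dam[carrying] = pup[carrying] + np.array([5.0, 5.0])
        dam[t > move_end] = nest + wander[t > move_end]
    elif truth["self_return"]:
        # dam parked far from both nest and pup path
        far = np.array([params.start_corner[0], params.nest_position[1]])
        dam = np.tile(far, (n_frames, 1)) + wander

    # --- occlusion windows ---------------------------------------------------
    occl_p = params.occlusion_prob
    hand = (t < truth["hand_exit_time"])
    pup_occluded = hand & (rng.random(n_frames) < max(occl_p, 0.0))
    if truth["success"] and not truth["self_return"]:
        carry_frames = (t >= move_start) & (t <= move_end)
        pup_occluded |= carry_frames & (rng.random(n_frames) < 0.5 * occl_p)
    pre = t < 0
    pup_occluded |= pre   # pup not yet in the cage

    # --- assemble the tracking table -----------------------------------------
    part_offsets = {
        "dam": np.array([[12.0, 0.0], [0.0, 0.0], [-14.0, 0.0]]),
        "pup": np.array([[6.0, 0.0], [0.0, 0.0], [-7.0, 0.0]]),
    }
    columns: dict[tuple[str, str], np.ndarray] = {}
    for role, path, occl in (
        ("dam", dam, np.zeros(n_frames, dtype=bool)),
        ("pup", pup, pup_occluded),
    ):
        parts = config.body_parts[role]
        offs = part_offsets[role][: len(parts)]
        blocks = _keypoint_block(rng, params, config, path, offs, occl)
        for j, part in enumerate(parts):
            pos, lk = blocks[j]
            columns[(part, "x")] = pos[:, 0]
            columns[(part, "y")] = pos[:, 1]
            columns[(part, "likelihood")] = lk
    nest_part = config.body_parts["nest"][0]
    nest_px = np.tile(nest * config.px_per_mm, (n_frames, 1))
    if params.track_noise_sd > 0:
        nest_px = nest_px + rng.normal(0, 0.5 * params.track_noise_sd, (n_frames, 2))
    columns[(nest_part, "x")] = nest_px[:, 0]
    columns[(nest_part, "y")] = nest_px[:, 1]
    columns[(nest_part, "likelihood")] = rng.beta(20, 0.5, n_frames)

    data = pd.DataFrame(columns)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    data.index = pd.RangeIndex(n_frames, name="frame")
    track = TrackingTable(
        data=data, fps=fps, px_per_mm=config.px_per_mm,
        roles={r: tuple(config.body_parts[r]) for r in ("dam", "pup", "nest")},
    )

    # --- call segments on the raw audio clock --------------------------------
    starts = truth["event_times"] + audio_offset
    stops = truth["event_stops"] + audio_offset
    # occasionally a pre-beep noise call, dropped by synchronization
    if rng.random() < 0.3 and audio_offset > 1.0:
        starts = np.insert(starts, 0, audio_offset - 0.8)
        stops = np.insert(stops, 0, audio_offset - 0.75)
    segments = USVSegmentTable.from_arrays(starts, stops)

    record = TrialRecord(
        dam_id=f"dam{dam_idx:03d}",
        pup_sex=sex,
        pnd=pnd,
        maternal_trial_seq=seq,
        condition=condition,
        cup_present=pnd != 5,
        beep_video_frame=beep_frame,
        beep_audio_time=audio_offset,
        hand_exit_time=truth["hand_exit_time"],
        manual_retrieval_time=truth["manual_retrieval_time"],
        manual_success=truth["manual_success"],
        trial_duration=duration,
    )
    truth_out = dict(truth)
    truth_out.update(
        dam_id=record.dam_id, pnd=pnd, maternal_trial_seq=seq, pup_sex=sex,
        condition=condition, d_start=d_start,
    )
    return SyntheticTrial(track=track, segments=segments, record=record,
                          truth=truth_out)


def iter_trials(params: SimParams, config: PipelineConfig):
    """Yield every full-resolution trial of the design, in design order."""
    for dam, pnd, seq, sex, condition in _trial_design(params):
        yield simulate_trial(params, config, dam, pnd, seq, sex, condition)


def simulate_cohort(
    params: SimParams, config: PipelineConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Write a full cohort bundle to ``out_dir``.

    Emits one tracking CSV and one segment CSV per trial, a metadata CSV,
    and a ground-truth CSV (for testing only — a real cohort has no such
    file).  Returns the ground-truth table.  Deterministic: the same seed
    yields a byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truths = [], []
    for trial in iter_trials(params, config):
        tid = trial.record.trial_id
        write_tracking_table(trial.track, out / f"tracking_{tid}.csv")
        write_usv_segments(trial.segments, out / f"usv_{tid}.csv")
        records.append(trial.record)
        row = {k: v for k, v in trial.truth.items()
               if k not in ("event_times", "event_stops")}
        row["trial_id"] = tid
        row["n_events"] = len(trial.truth["event_times"])
        truths.append(row)
    write_trial_metadata(records, out / "metadata.csv")
    truth_df = pd.DataFrame(truths)
    if truth_df.empty:
        truth_df = pd.DataFrame(
            columns=["trial_id", "dam_id", "pnd", "maternal_trial_seq",
                     "pup_sex", "condition", "true_rate", "retrieval_time",
                     "success", "self_return", "hand_exit_time",
                     "manual_retrieval_time", "manual_success", "d_start",
                     "n_events"]
        )
    truth_df.to_csv(out / "ground_truth.csv", index=False)
    return truth_df
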