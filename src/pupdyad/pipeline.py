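"""End-to-end per-trial analysis: sync -> retrieval estimate -> features.

Glue between the stage modules: windows the raw tracking table at the beep,
synchronizes the call segments, runs the trajectory QC chain and the
retrieval estimator, and assembles one feature row per trial.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .config import PipelineConfig
from .features import compute_trial_features
from .io import (
    TrackingTable,
    TrialRecord,
    USVSegmentTable,
    read_tracking_table,
    read_trial_metadata,
    read_usv_segments,
)
from .retrieval import estimate_trial
from .sync import synchronize_segments

__all__ = ["analyze_trial", "analyze_cohort", "load_cohort"]


def analyze_trial(
    track: TrackingTable,
    segments: USVSegmentTable,
    record: TrialRecord,
    config: PipelineConfig,
) -> dict:
    """Analyze one trial from raw-clock inputs; returns one feature row.

    ``track`` is on the raw video clock (the beep frame is taken from the
    record); ``segments`` are on the raw audio clock.
    """
    n_trial = int(round(config.trial_duration * config.video_fps))
    if record.beep_video_frame >= track.n_frames:
        raise ValueError(
            f"{record.trial_id}: beep frame {record.beep_video_frame} beyond "
            f"the recording ({track.n_frames} frames)"
        )
    windowed = track.window(record.beep_video_frame, n_trial)
    synced, sync, n_removed = synchronize_segments(segments, record, config)
    est, ds = estimate_trial(windowed, config)
    feats = compute_trial_features(
        synced, est.retrieval_time, est.success, config, flags=est.flags
    )
    row = {
        "trial_id": record.trial_id,
        "dam_id": record.dam_id,
        "pup_sex": record.pup_sex,
        "pnd": record.pnd,
        "maternal_trial_seq": record.maternal_trial_seq,
        "condition": record.condition,
        "manual_retrieval_time": record.manual_retrieval_time,
        "manual_success": record.manual_success,
        "self_return_flag": est.self_return_flag,
        "video_offset": sync.video_offset,
        "audio_offset": sync.audio_offset,
        "n_usv_removed_hand": n_removed,
        "nest_entry_radius": config.nest_entry_radius,
    }
    row.update(feats.to_dict())
    return row


def analyze_cohort(
    trials: Iterable[tuple[TrackingTable, USVSegmentTable, TrialRecord]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Analyze a sequence of trials into one feature table."""
    return pd.DataFrame(
        [analyze_trial(track, segments, record, config)
         for track, segments, record in trials]
    )


def load_cohort(
    directory: str | Path, config: PipelineConfig
) -> Iterator[tuple[TrackingTable, USVSegmentTable, TrialRecord]]:
    """Load a cohort bundle (metadata.csv + per-trial CSVs) lazily."""
    directory = Path(directory)
    records = read_trial_metadata(directory / "metadata.csv", config)
    for record in records:
        track = read_tracking_table(
            directory / f"tracking_{record.trial_id}.csv", config
        )
        segments = read_usv_segments(directory / f"usv_{record.trial_id}.csv")
        yield track, segments, record
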