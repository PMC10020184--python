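"""Beep-anchored synchronization of video and audio streams.

Video and audio are recorded by separate devices; both capture the trial
start beep.  The trial clock puts t = 0 at the beep in both streams and ends
the trial ``trial_duration`` seconds later.  Because the audio stream is
trimmed at its own frame granularity (25 fps), the alignment carries a
one-trim-frame uncertainty (40 ms at defaults), which is reported rather
than resampled away.

Vocal segments emitted while the experimenter's hand is still in the cage
(placing the pup) are artefact-prone and removed whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import TrialRecord, USVSegmentTable

__all__ = [
    "SyncMap",
    "build_sync_map",
    "to_trial_clock",
    "censor_hand_interval",
    "clip_to_trial",
    "synchronize_segments",
]


@dataclass(frozen=True)
class SyncMap:
    """Offsets mapping raw stream clocks onto the shared trial clock."""

    video_offset: float       # beep time on the raw video clock (s)
    audio_offset: float       # beep time on the raw audio clock (s)
    trial_duration: float     # s
    alignment_uncertainty: float  # one audio trim frame (s)

    def __post_init__(self) -> None:
        if self.video_offset < 0 or self.audio_offset < 0:
            raise ValueError("stream offsets must be non-negative")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")

    def video_to_trial(self, t: float) -> float:
        return t - self.video_offset

    def trial_to_video(self, t: float) -> float:
        return t + self.video_offset


def build_sync_map(record: TrialRecord, config: PipelineConfig) -> SyncMap:
    """Anchor the trial clock at the beep in both streams.

    t = 0 is the first video frame with an audible beep (and the audio
    sampling point before the beep); the trial ends ``trial_duration``
    seconds later.
    """
    video_offset = record.beep_video_frame / config.video_fps
    return SyncMap(
        video_offset=video_offset,
        audio_offset=record.beep_audio_time,
        trial_duration=config.trial_duration,
        alignment_uncertainty=1.0 / config.audio_trim_fps,
    )


def to_trial_clock(segments: USVSegmentTable, sync: SyncMap) -> USVSegmentTable:
    """Shift segments from the raw audio clock onto the trial clock.

    Segments ending at or before the beep are dropped; a segment straddling
    the beep is truncated to start at 0.
    """
    df = segments.df.copy()
    df["start"] = df["start"] - sync.audio_offset
    df["stop"] = df["stop"] - sync.audio_offset
    df = df[df["stop"] > 0.0]
    df.loc[df["start"] < 0.0, "start"] = 0.0
    return USVSegmentTable(df.reset_index(drop=True))


def censor_hand_interval(
    segments: USVSegmentTable, hand_exit_time: float
) -> tuple[USVSegmentTable, int]:
    """Remove every segment overlapping [0, hand_exit_time).

    Calls detected while the experimenter's hand is in the cage are removed
    whole (a partial call is not a meaningful unit).  Returns the filtered
    table and the number of segments removed.
    """
    if hand_exit_time < 0:
        raise ValueError(f"hand_exit_time must be non-negative, got {hand_exit_time}")
    df = segments.df
    overlaps = (df["start"] < hand_exit_time) & (df["stop"] > 0.0)
    n_removed = int(overlaps.sum())
    return USVSegmentTable(df[~overlaps].reset_index(drop=True)), n_removed


def clip_to_trial(segments: USVSegmentTable, trial_duration: float) -> USVSegmentTable:
    """Restrict segments to the trial window [0, trial_duration).

    Segments starting at or after the trial end are dropped; a straddling
    segment is truncated at the trial end.
    """
    df = segments.df.copy()
    df = df[df["start"] < trial_duration]
    df.loc[df["stop"] > trial_duration, "stop"] = trial_duration
    return USVSegmentTable(df.reset_index(drop=True))


def synchronize_segments(
    segments: USVSegmentTable, record: TrialRecord, config: PipelineConfig
) -> tuple[USVSegmentTable, SyncMap, int]:
    """Full segment synchronization: shift, hand-interval censor, clip.

    Convenience wrapper running the three stages in order; afterwards all
    segments lie in [0, trial_duration) and none overlaps the hand interval.
    """
    sync = build_sync_map(record, config)
    on_trial = to_trial_clock(segments, sync)
    censored, n_removed = censor_hand_interval(on_trial, record.hand_exit_time)
    clipped = clip_to_trial(censored, sync.trial_duration)
    return clipped, sync, n_removed


def sync_report(
    sync: SyncMap, record: TrialRecord, n_removed: int
) -> pd.Series:
    """One row of the per-trial sync report."""
    return pd.Series(
        {
            "trial_id": record.trial_id,
            "video_offset": sync.video_offset,
            "audio_offset": sync.audio_offset,
            "alignment_uncertainty": sync.alignment_uncertainty,
            "hand_exit_time": record.hand_exit_time,
            "n_usv_removed_hand": n_removed,
        }
    )
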