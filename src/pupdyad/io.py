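"""Readers and writers for the pipeline's file dialects.

Three dialects are handled, all comma-separated UTF-8 with dot decimals:

* pose-tracking tables in the DeepLabCut 3-header layout (scorer /
  bodyparts / coords, then one row per frame with x, y, likelihood per
  body part);
* vocalization segment tables in the audio segmenter's annotation export
  layout (``name, start_seconds, stop_seconds``);
* flat per-trial metadata tables.

Loading never silently coerces: malformed cells are rejected with row and
column coordinates in the error message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "TrackingTable",
    "USVSegmentTable",
    "TrialRecord",
    "read_tracking_table",
    "write_tracking_table",
    "read_usv_segments",
    "write_usv_segments",
    "read_trial_metadata",
    "write_trial_metadata",
]

_COORDS = ("x", "y", "likelihood")


@dataclass
class TrackingTable:
    """Per-frame keypoint coordinates and likelihoods for one trial.

    ``data`` has a 0-based contiguous frame index and two-level columns
    ``(body_part, coord)`` with coord in {x, y, likelihood}.  ``roles``
    partitions the body parts into the dam set, the pup set and the single
    nest point.
    """

    data: pd.DataFrame
    fps: float
    px_per_mm: float
    roles: dict[str, tuple[str, ...]]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.data.columns.get_level_values(0).unique())

    def times(self) -> np.ndarray:
        """Frame times in seconds on the table's own clock."""
        return self.data.index.to_numpy(dtype=float) / self.fps

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) array of pixel coordinates for one body part."""
        return self.data[part][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, parts: Sequence[str]) -> np.ndarray:
        """(n_frames, len(parts)) array of keypoint likelihoods."""
        return np.column_stack(
            [self.data[(p, "likelihood")].to_numpy(dtype=float) for p in parts]
        )

    def window(self, start_frame: int, n_frames: int) -> "TrackingTable":
        """Slice frames [start_frame, start_frame + n_frames) and re-zero."""
        sub = self.data.iloc[start_frame : start_frame + n_frames].reset_index(drop=True)
        sub.index.name = self.data.index.name
        return replace(self, data=sub)


@dataclass
class USVSegmentTable:
    """Ordered vocal segments, half-open intervals [start, stop) in seconds."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["name", "start", "stop"])
    )

    def __post_init__(self) -> None:
        df = self.df
        missing = {"name", "start", "stop"} - set(df.columns)
        if missing:
            raise ValueError(f"segment table lacks columns {sorted(missing)}")
        df = df.loc[:, ["name", "start", "stop"]].copy()
        df["start"] = df["start"].astype(float)
        df["stop"] = df["stop"].astype(float)
        bad = df.index[df["stop"] <= df["start"]]
        if len(bad):
            raise ValueError(
                f"segment row {bad[0]}: stop ({df.loc[bad[0], 'stop']}) must "
                f"exceed start ({df.loc[bad[0], 'start']})"
            )
        self.df = df.sort_values("start", kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def stops(self) -> np.ndarray:
        return self.df["stop"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self.stops - self.starts

    @classmethod
    def from_arrays(
        cls,
        starts: Iterable[float],
        stops: Iterable[float],
        name: str = "usv",
    ) -> "USVSegmentTable":
        starts = np.asarray(list(starts), dtype=float)
        stops = np.asarray(list(stops), dtype=float)
        return cls(pd.DataFrame({"name": name, "start": starts, "stop": stops}))


_SEXES = ("female", "male")
_PNDS = (5, 7, 9, 11, 13)


@dataclass
class TrialRecord:
    """Metadata for one pup-retrieval trial."""

    dam_id: str
    pup_sex: str
    pnd: int
    maternal_trial_seq: int
    condition: str
    cup_present: bool
    beep_video_frame: int
    beep_audio_time: float
    hand_exit_time: float
    manual_retrieval_time: float
    manual_success: int
    trial_duration: float = 100.0

    def __post_init__(self) -> None:
        if self.pup_sex not in _SEXES:
            raise ValueError(f"pup_sex must be one of {_SEXES}, got {self.pup_sex!r}")
        if self.pnd not in _PNDS:
            raise ValueError(f"pnd must be one of {_PNDS}, got {self.pnd!r}")
        max_seq = 6 if self.pnd == 5 else 4
        if not 1 <= self.maternal_trial_seq <= max_seq:
            raise ValueError(
                f"maternal_trial_seq {self.maternal_trial_seq} outside "
                f"[1, {max_seq}] for PND{self.pnd}"
            )
        if self.cup_present != (self.pnd != 5):
            raise ValueError(
                f"cup_present={self.cup_present} inconsistent with PND{self.pnd}: "
                "the cup is absent on PND5 and present on PND7-13"
            )
        if self.beep_video_frame < 0 or self.beep_audio_time < 0:
            raise ValueError("beep anchors must be non-negative")
        if not 0 <= self.hand_exit_time < self.trial_duration:
            raise ValueError(
                f"hand_exit_time {self.hand_exit_time} outside "
                f"[0, {self.trial_duration})"
            )
        if self.manual_success not in (0, 1):
            raise ValueError(f"manual_success must be 0 or 1, got {self.manual_success!r}")
        if not 0 <= self.manual_retrieval_time <= self.trial_duration:
            raise ValueError(
                f"manual_retrieval_time {self.manual_retrieval_time} outside "
                f"[0, {self.trial_duration}]"
            )
        if self.manual_success == 0 and self.manual_retrieval_time != self.trial_duration:
            raise ValueError(
                "manual_success=0 requires manual_retrieval_time == trial_duration "
                f"({self.trial_duration}); got {self.manual_retrieval_time} "
                "(non-retrieved pups are censored at the trial end)"
            )

    @property
    def trial_id(self) -> str:
        return f"{self.dam_id}_pnd{self.pnd}_t{self.maternal_trial_seq}"


# ---------------------------------------------------------------------------
# tracking tables
# ---------------------------------------------------------------------------

def read_tracking_table(path: str | Path, config: PipelineConfig) -> TrackingTable:
    """Read a 3-header pose-tracking CSV and partition parts into roles.

    Raises ``ValueError`` on malformed headers, a non-monotone frame index,
    body parts not present in the configured role map, or likelihoods
    outside [0, 1] (reported with frame/part coordinates).
    """
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, IndexError) as exc:
        raise ValueError(f"{path}: malformed 3-header tracking CSV: {exc}") from exc
    if raw.columns.nlevels != 3:
        raise ValueError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    # drop the scorer level; it carries no information downstream
    raw.columns = raw.columns.droplevel(0)
    raw.columns = raw.columns.set_names([None, None])
    coords = set(raw.columns.get_level_values(1))
    if not coords <= set(_COORDS):
        raise ValueError(
            f"{path}: unknown coordinate labels {sorted(coords - set(_COORDS))}; "
            "expected x/y/likelihood"
        )
    frames = raw.index.to_numpy()
    if len(frames) and (
        not np.issubdtype(np.asarray(frames).dtype, np.number)
        or np.any(np.diff(frames) <= 0)
    ):
        raise ValueError(f"{path}: frame index must be numeric and strictly increasing")
    raw.index = pd.RangeIndex(len(raw), name="frame")

    known = {p for parts in config.body_parts.values() for p in parts}
    parts = list(dict.fromkeys(raw.columns.get_level_values(0)))
    unknown = [p for p in parts if p not in known]
    if unknown:
        raise ValueError(
            f"{path}: body part(s) {unknown} not present in the configured "
            f"body-part role map (known: {sorted(known)})"
        )
    for part in parts:
        for coord in _COORDS:
            if (part, coord) not in raw.columns:
                raise ValueError(f"{path}: body part {part!r} lacks a {coord!r} column")
        lk = raw[(part, "likelihood")].to_numpy(dtype=float)
        bad = np.flatnonzero((lk < 0) | (lk > 1))
        if bad.size:
            raise ValueError(
                f"{path}: likelihood out of range at frame {bad[0]}, "
                f"body part {part!r} ({lk[bad[0]]!r})"
            )
    roles = {
        role: tuple(p for p in config.body_parts[role] if p in parts)
        for role in ("dam", "pup", "nest")
    }
    raw = raw.astype(float)
    return TrackingTable(
        data=raw, fps=config.video_fps, px_per_mm=config.px_per_mm, roles=roles
    )


def write_tracking_table(
    table: TrackingTable, path: str | Path, scorer: str = "pupdyad"
) -> None:
    """Write a TrackingTable in the canonical 3-header CSV dialect."""
    out = table.data.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in out.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.index.name = None
    out.to_csv(path)


# ---------------------------------------------------------------------------
# vocalization segments
# ---------------------------------------------------------------------------

def read_usv_segments(path: str | Path) -> USVSegmentTable:
    """Read an annotation CSV (name, start_seconds, stop_seconds).

    An empty file body yields an empty table.  A row with stop <= start is
    rejected with its row number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return USVSegmentTable()
    if df.empty and not len(df.columns):
        return USVSegmentTable()
    rename = {"start_seconds": "start", "stop_seconds": "stop"}
    df = df.rename(columns=rename)
    missing = {"name", "start", "stop"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: segment table lacks column(s) {sorted(missing)} "
            "(expected name, start_seconds, stop_seconds)"
        )
    for col in ("start", "stop"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0]}"
            )
        df[col] = vals
    bad = df.index[df["stop"] <= df["start"]]
    if len(bad):
        raise ValueError(
            f"{path}: row {bad[0]}: stop ({df.loc[bad[0], 'stop']}) must exceed "
            f"start ({df.loc[bad[0], 'start']})"
        )
    return USVSegmentTable(df[["name", "start", "stop"]])


def write_usv_segments(table: USVSegmentTable, path: str | Path) -> None:
    out = table.df.rename(columns={"start": "start_seconds", "stop": "stop_seconds"})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trial metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "dam_id",
    "pup_sex",
    "pnd",
    "maternal_trial_seq",
    "condition",
    "cup_present",
    "beep_video_frame",
    "beep_audio_time",
    "hand_exit_time",
    "manual_retrieval_time",
    "manual_success",
]


def read_trial_metadata(
    path: str | Path, config: PipelineConfig | None = None
) -> list[TrialRecord]:
    """Read per-trial metadata; every record invariant is validated at load."""
    duration = config.trial_duration if config is not None else 100.0
    df = pd.read_csv(path)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata lacks column(s) {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                TrialRecord(
                    dam_id=str(row["dam_id"]),
                    pup_sex=str(row["pup_sex"]),
                    pnd=int(row["pnd"]),
                    maternal_trial_seq=int(row["maternal_trial_seq"]),
                    condition=str(row["condition"]),
                    cup_present=bool(row["cup_present"]),
                    beep_video_frame=int(row["beep_video_frame"]),
                    beep_audio_time=float(row["beep_audio_time"]),
                    hand_exit_time=float(row["hand_exit_time"]),
                    manual_retrieval_time=float(row["manual_retrieval_time"]),
                    manual_success=int(row["manual_success"]),
                    trial_duration=duration,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_trial_metadata(records: Sequence[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _META_COLUMNS} for r in records])
    if df.empty:
        df = pd.DataFrame(columns=_META_COLUMNS)
    df.to_csv(path, index=False)
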