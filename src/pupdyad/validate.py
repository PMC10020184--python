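"""Automated-vs-manual agreement and detector evaluation.

Retrieval validation treats the manual score as ground truth and the
automated estimate as the prediction, with **positive class = "not
retrieved"** — the convention under which a confusion table's printed
sensitivity and specificity are reproduced from its cells.  The accuracy
confidence interval is the exact (Clopper-Pearson) binomial interval.

Segment detection is evaluated sample-wise on a fine time grid (1 ms by
default): each grid cell is labelled call/noise by the reference and the
predicted tables, and per-class precision, recall and F1 plus overall
accuracy follow from the grid confusion counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import USVSegmentTable

__all__ = [
    "ConfusionSummary",
    "SegmentEvalResult",
    "confusion_summary",
    "flag_discrepancies",
    "apply_corrections",
    "per_day_correlation",
    "segment_detection_eval",
    "f1_score",
    "clopper_pearson",
]


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0; got k={k}, n={n}")
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 agreement of automated vs manual retrieval success.

    Positive class is "not retrieved" (success = 0); manual scores are the
    reference.  tp: both not retrieved; tn: both retrieved; fp: automated
    not retrieved but manually retrieved; fn: automated retrieved but
    manually not retrieved.  Metrics are percentages; ci is the exact 95%
    binomial interval on accuracy.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_disagreements(self) -> int:
        return self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy_ci(self) -> tuple[float, float]:
        lo, hi = clopper_pearson(self.tp + self.tn, self.total)
        return 100.0 * lo, 100.0 * hi

    def report(self) -> pd.Series:
        lo, hi = self.accuracy_ci
        return pd.Series(
            {
                "tp_not_retrieved_both": self.tp,
                "fp_auto_not_manual_yes": self.fp,
                "fn_auto_yes_manual_not": self.fn,
                "tn_retrieved_both": self.tn,
                "accuracy_pct": round(self.accuracy, 1),
                "sensitivity_pct": round(self.sensitivity, 1),
                "specificity_pct": round(self.specificity, 1),
                "ci_low_pct": round(lo, 1),
                "ci_high_pct": round(hi, 1),
            }
        )


def confusion_summary(
    manual: np.ndarray, automated: np.ndarray
) -> ConfusionSummary:
    """Cross-tabulate automated vs manual success labels.

    Labels are the 0/1 success coding (1 = retrieved); the positive class
    of the summary is "not retrieved" (label 0).
    """
    manual = np.asarray(manual)
    automated = np.asarray(automated)
    if manual.shape != automated.shape:
        raise ValueError(
            f"label vectors differ in length: {manual.shape} vs {automated.shape}"
        )
    for name, v in (("manual", manual), ("automated", automated)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0/1 success codes")
    return ConfusionSummary(
        tp=int(((manual == 0) & (automated == 0)).sum()),
        fp=int(((manual == 1) & (automated == 0)).sum()),
        fn=int(((manual == 0) & (automated == 1)).sum()),
        tn=int(((manual == 1) & (automated == 1)).sum()),
    )


def flag_discrepancies(
    manual_times: np.ndarray,
    automated_times: np.ndarray,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Flag trials where |manual - automated| exceeds the threshold (30 s).

    Returns a per-trial table with the signed difference (automated -
    manual) and the flag; the frame carries the mean and SD of the
    difference as attributes ``mean_diff`` / ``sd_diff``.
    """
    manual_times = np.asarray(manual_times, dtype=float)
    automated_times = np.asarray(automated_times, dtype=float)
    if manual_times.shape != automated_times.shape:
        raise ValueError("paired time vectors differ in length")
    diff = automated_times - manual_times
    out = pd.DataFrame(
        {
            "manual_time": manual_times,
            "automated_time": automated_times,
            "difference": diff,
            "flagged": np.abs(diff) > config.flag_threshold,
        }
    )
    out.attrs["mean_diff"] = float(diff.mean()) if len(diff) else float("nan")
    out.attrs["sd_diff"] = float(diff.std(ddof=1)) if len(diff) > 1 else float("nan")
    return out


def apply_corrections(
    dataset: pd.DataFrame, decisions: dict[int, str]
) -> pd.DataFrame:
    """Apply per-flag review decisions to a paired manual/automated dataset.

    ``dataset`` needs columns manual_time, automated_time, manual_success,
    automated_success and flagged.  Decisions map row index to one of
    ``accept`` (keep the automated estimate), ``use_manual`` (overwrite the
    automated time/success with the manual score) or ``drop_self_return``
    (remove the trial).  Every flagged row must have a decision.  The
    result carries an audit column ``decision``.
    """
    flagged_idx = set(dataset.index[dataset["flagged"]])
    missing = flagged_idx - set(decisions)
    if missing:
        raise ValueError(f"flagged trial(s) without a decision: {sorted(missing)[:5]}")
    unknown = set(decisions) - set(dataset.index)
    if unknown:
        raise ValueError(f"decisions refer to unknown rows: {sorted(unknown)[:5]}")
    out = dataset.copy()
    out["decision"] = "unflagged"
    for idx, decision in decisions.items():
        if decision not in ("accept", "use_manual", "drop_self_return"):
            raise ValueError(f"unknown decision {decision!r} for row {idx}")
        out.loc[idx, "decision"] = decision
        if decision == "use_manual":
            out.loc[idx, "automated_time"] = out.loc[idx, "manual_time"]
            out.loc[idx, "automated_success"] = out.loc[idx, "manual_success"]
    drop = [i for i, d in decisions.items() if d == "drop_self_return"]
    return out.drop(index=drop)


def per_day_correlation(
    manual_times: np.ndarray,
    automated_times: np.ndarray,
    day_labels: np.ndarray,
) -> pd.DataFrame:
    """Pearson r of manual vs automated times, overall and per test day.

    Groups with fewer than 3 pairs or zero variance yield a missing r with
    a warning.
    """
    df = pd.DataFrame(
        {
            "manual": np.asarray(manual_times, dtype=float),
            "automated": np.asarray(automated_times, dtype=float),
            "day": np.asarray(day_labels),
        }
    )
    rows = []
    groups = [("overall", df)] + [
        (str(day), sub) for day, sub in df.groupby("day", sort=True)
    ]
    for label, sub in groups:
        r = np.nan
        if len(sub) < 3:
            warnings.warn(f"group {label}: fewer than 3 pairs; r missing",
                          UserWarning, stacklevel=2)
        elif sub["manual"].nunique() < 2 or sub["automated"].nunique() < 2:
            warnings.warn(f"group {label}: zero variance; r missing",
                          UserWarning, stacklevel=2)
        else:
            r = float(stats.pearsonr(sub["manual"], sub["automated"]).statistic)
        rows.append({"group": label, "n": len(sub), "pearson_r": r})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SegmentEvalResult:
    """Grid-based detector evaluation (percentages)."""

    precision_usv: float
    recall_usv: float
    f1_usv: float
    precision_noise: float
    recall_noise: float
    f1_noise: float
    accuracy: float
    grid_step: float


def _merge_to_grid(
    table: USVSegmentTable, edges: np.ndarray, where: str
) -> np.ndarray:
    """Boolean call/noise labelling of grid cells; merges overlaps."""
    starts, stops = table.starts, table.stops
    if len(starts) > 1 and np.any(starts[1:] < stops[:-1]):
        warnings.warn(
            f"overlapping segments in the {where} table merged before "
            "evaluation", UserWarning, stacklevel=3,
        )
    # label a cell "call" if its midpoint lies inside any [start, stop)
    mids = (edges[:-1] + edges[1:]) / 2.0
    idx = np.searchsorted(starts, mids, side="right") - 1
    inside = np.zeros(len(mids), dtype=bool)
    has = idx >= 0
    # a midpoint may fall inside an earlier, longer segment than the one
    # found by searchsorted; use running max of stops to handle overlaps
    run_stop = np.maximum.accumulate(stops) if len(stops) else stops
    inside[has] = mids[has] < run_stop[idx[has]]
    return inside


def segment_detection_eval(
    reference: USVSegmentTable,
    predicted: USVSegmentTable,
    config: PipelineConfig,
) -> SegmentEvalResult:
    """Sample-wise detector evaluation on a fine time grid.

    The trial window [0, trial_duration) is discretized at
    ``eval_grid_step`` (1 ms); each cell is labelled call/noise by each
    table, and precision/recall/F1 per class plus overall accuracy are
    computed from the grid confusion counts.
    """
    step = config.eval_grid_step
    n_cells = int(round(config.trial_duration / step))
    edges = np.arange(n_cells + 1) * step
    ref = _merge_to_grid(reference, edges, "reference")
    pred = _merge_to_grid(predicted, edges, "predicted")

    def prf(ref_pos: np.ndarray, pred_pos: np.ndarray) -> tuple[float, float, float]:
        tp = int((ref_pos & pred_pos).sum())
        fp = int((~ref_pos & pred_pos).sum())
        fn = int((ref_pos & ~pred_pos).sum())
        p = 100.0 * tp / (tp + fp) if tp + fp else 100.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 100.0
        return p, r, f1_score(p, r)

    p_u, r_u, f_u = prf(ref, pred)
    p_n, r_n, f_n = prf(~ref, ~pred)
    acc = 100.0 * float((ref == pred).mean())
    return SegmentEvalResult(
        precision_usv=p_u, recall_usv=r_u, f1_usv=f_u,
        precision_noise=p_n, recall_noise=r_n, f1_noise=f_n,
        accuracy=acc, grid_step=step,
    )
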