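"""Bidirectionality and repeatability statistics on per-trial features.

Two regression surfaces quantify the call <-> retrieval coupling:

* a binomial (logit) regression of retrieval success on a focal vocal
  feature plus the standard covariate set — pup sex, test day and
  experimental condition as fixed effects, maternal trial sequence as a
  continuous covariate;
* a Cox proportional-hazards regression of time-to-retrieval, with
  non-retrieved trials censored at the trial end (100 s) and the same
  covariates; the maternal-trial hazard ratio indexes within-day maternal
  learning.

Exponentiated coefficients are reported under the precise name for each
model: odds ratios for the logit model, hazard ratios for the Cox model.
Reference levels are sex = female, day = PND5 and the first condition in
alphabetical order.  Ties in the partial likelihood use the Efron
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_success_model",
    "fit_latency_model",
    "survival_curves_by_trial",
    "repeatability_matrix",
    "exclude_poor_retrievers",
    "sex_contrast",
]

_FOCALS = ("usv_rate", "mean_usv_duration", "n_usv_first_10s")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what."""

    focal: str = "usv_rate"
    censoring_time: float = 100.0
    cluster_robust: bool = False   # optional cluster-robust SEs by dam
    covariate_factors: tuple[str, ...] = ("pup_sex", "pnd", "condition")
    covariate_continuous: tuple[str, ...] = ("maternal_trial_seq",)

    def __post_init__(self) -> None:
        if self.focal not in _FOCALS:
            raise ValueError(f"focal must be one of {_FOCALS}, got {self.focal!r}")
        if self.censoring_time <= 0:
            raise ValueError("censoring_time must be positive")


@dataclass
class ModelResult:
    """Per-term estimates of one fitted model."""

    model_kind: str                 # "binomial-logit" or "proportional-hazards"
    table: pd.DataFrame             # index: term; estimate, exp_estimate, se, p
    n_used: int
    n_events: int
    notes: list[str] = field(default_factory=list)

    @property
    def focal_row(self) -> pd.Series:
        return self.table.iloc[0]

    def exp_estimate(self, term: str) -> float:
        return float(self.table.loc[term, "exp_estimate"])


def _design(
    features: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Index, list[str]]:
    """Build the numeric design matrix (no intercept) with reference coding."""
    notes: list[str] = []
    df = features.copy()
    if spec.focal == "n_usv_first_10s":
        early = df["retrieval_time"] < 10.0
        n_excl = int(early.sum())
        if n_excl:
            notes.append(f"excluded {n_excl} trial(s) retrieved before 10 s")
        df = df[~early]
    df = df.dropna(subset=[spec.focal])
    X = pd.DataFrame(index=df.index)
    X[spec.focal] = df[spec.focal].astype(float)
    for col in spec.covariate_continuous:
        X[col] = df[col].astype(float)
    refs = {"pup_sex": "female", "pnd": 5}
    for col in spec.covariate_factors:
        levels = sorted(df[col].unique(), key=str)
        ref = refs.get(col, levels[0])
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        for lev in levels[1:]:
            X[f"{col}[{lev}]"] = (df[col] == lev).astype(float)
    # drop aliased (collinear) columns, keeping the earliest
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(col)
        else:
            notes.append(f"dropped aliased term {col}")
            warnings.warn(f"dropped aliased design term {col}", UserWarning,
                          stacklevel=3)
    X = X[keep]
    return X, df.index, notes


def fit_success_model(features: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Binomial (logit) regression of retrieval success on the focal feature.

    The exponentiated focal coefficient is the odds ratio per unit of the
    focal feature (e.g. per 1 call/s of rate).  Refuses degenerate designs:
    constant success or complete separation.
    """
    X, rows, notes = _design(features, spec)
    y = features.loc[rows, "success"].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("success must be coded 0/1")
    if y.nunique() < 2:
        raise ValueError(
            "retrieval success is constant; the binomial model is not "
            "identifiable (no variance / complete separation)"
        )
    Xc = sm.add_constant(X, prepend=True)
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            if spec.cluster_robust:
                res = model.fit(
                    cov_type="cluster",
                    cov_kwds={"groups": features.loc[rows, "dam_id"]},
                )
            else:
                res = model.fit()
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise ValueError(f"complete separation in the success model: {exc}") from exc
    terms = [c for c in Xc.columns if c != "const"]
    table = pd.DataFrame(
        {
            "estimate": res.params[terms],
            "exp_estimate": np.exp(res.params[terms]),
            "se": res.bse[terms],
            "p": res.pvalues[terms],
        }
    )
    return ModelResult(
        model_kind="binomial-logit",
        table=table,
        n_used=int(res.nobs),
        n_events=int(y.sum()),
        notes=notes,
    )


def fit_latency_model(features: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Cox proportional-hazards regression of time-to-retrieval.

    Non-retrieved trials are censored at ``censoring_time``; the event
    indicator is retrieval success.  Exponentiated coefficients are hazard
    ratios (e.g. HR > 1 for maternal trial sequence means later trials are
    retrieved faster).  Refuses all-censored data.
    """
    X, rows, notes = _design(features, spec)
    t = features.loc[rows, "retrieval_time"].astype(float)
    e = features.loc[rows, "success"].astype(int)
    if (t <= 0).any() or (t > spec.censoring_time).any():
        raise ValueError(
            f"retrieval_time must lie in (0, {spec.censoring_time}]"
        )
    if e.sum() == 0:
        raise ValueError("all observations censored; the hazard model is not fittable")
    data = X.copy()
    data["retrieval_time"] = t
    data["success"] = e
    cph = CoxPHFitter()
    kwargs = {}
    if spec.cluster_robust:
        data = data.assign(dam_id=features.loc[rows, "dam_id"].to_numpy())
        kwargs = {"cluster_col": "dam_id", "robust": True}
    cph.fit(data, duration_col="retrieval_time", event_col="success", **kwargs)
    table = pd.DataFrame(
        {
            "estimate": cph.params_,
            "exp_estimate": np.exp(cph.params_),
            "se": cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    table = table.reindex(list(X.columns))
    return ModelResult(
        model_kind="proportional-hazards",
        table=table,
        n_used=len(data),
        n_events=int(e.sum()),
        notes=notes,
    )


def survival_curves_by_trial(
    features: pd.DataFrame, censoring_time: float = 100.0
) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) retrieval curves per maternal trial.

    Returns a long step-function table (maternal_trial_seq, time,
    survival), where survival is the estimated probability of *not yet*
    being retrieved.  Strata with fewer than 2 trials are omitted with a
    warning.
    """
    out = []
    for seq, sub in features.groupby("maternal_trial_seq", sort=True):
        if len(sub) < 2:
            warnings.warn(f"maternal trial {seq}: <2 trials; stratum omitted",
                          UserWarning, stacklevel=2)
            continue
        km = KaplanMeierFitter()
        km.fit(sub["retrieval_time"], event_observed=sub["success"])
        sf = km.survival_function_
        step = pd.DataFrame(
            {
                "maternal_trial_seq": seq,
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(),
            }
        )
        out.append(step)
    if not out:
        return pd.DataFrame(columns=["maternal_trial_seq", "time", "survival"])
    return pd.concat(out, ignore_index=True)


def repeatability_matrix(features: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Pearson correlations of a trait's dam x sex means across test days.

    The trait is averaged to dam x sex units per day; every day pair gets a
    Pearson r over units with data on both days.  Pairs with fewer than 3
    complete units are missing; pairwise unit counts are attached as
    ``attrs["n_pairs"]``.  The diagonal is 1.
    """
    if trait not in features.columns:
        raise KeyError(f"trait {trait!r} not in the feature table")
    unit = (
        features.groupby(["dam_id", "pup_sex", "pnd"], sort=True)[trait]
        .mean()
        .unstack("pnd")
    )
    days = list(unit.columns)
    corr = pd.DataFrame(np.eye(len(days)), index=days, columns=days)
    counts = pd.DataFrame(0, index=days, columns=days, dtype=int)
    for i, a in enumerate(days):
        counts.loc[a, a] = int(unit[a].notna().sum())
        for b in days[i + 1 :]:
            sub = unit[[a, b]].dropna()
            counts.loc[a, b] = counts.loc[b, a] = len(sub)
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                continue
            r = float(sps.pearsonr(sub[a], sub[b]).statistic)
            corr.loc[a, b] = corr.loc[b, a] = r
    corr.attrs["n_pairs"] = counts
    return corr


def exclude_poor_retrievers(
    features: pd.DataFrame, config
) -> tuple[pd.DataFrame, list[str]]:
    """Remove dams retrieving on fewer than half of their trials.

    The rule is strict: a dam at exactly the cutoff (e.g. 2/4) is kept.
    Returns the filtered table and the excluded dam list.
    """
    frac = features.groupby("dam_id")["success"].mean()
    excluded = sorted(frac.index[frac < config.poor_retriever_cutoff].tolist())
    return features[~features["dam_id"].isin(excluded)].copy(), excluded


def sex_contrast(features: pd.DataFrame, trait: str) -> tuple[float, float]:
    """Male-vs-female contrast for a trait from the covariate-adjusted model.

    Fits an ordinary linear model of the trait on sex (reference female)
    plus test day, condition and maternal trial sequence, and returns the
    male coefficient (in the trait's units; negative = males lower) with
    its p-value.  Refuses single-sex data.
    """
    df = features.dropna(subset=[trait])
    if df["pup_sex"].nunique() < 2:
        raise ValueError("both pup sexes are required for a sex contrast")
    X = pd.DataFrame(index=df.index)
    X["male"] = (df["pup_sex"] == "male").astype(float)
    X["maternal_trial_seq"] = df["maternal_trial_seq"].astype(float)
    for col in ("pnd", "condition"):
        levels = sorted(df[col].unique(), key=str)
        for lev in levels[1:]:
            X[f"{col}[{lev}]"] = (df[col] == lev).astype(float)
    res = sm.OLS(df[trait].astype(float), sm.add_constant(X)).fit()
    return float(res.params["male"]), float(res.pvalues["male"])
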