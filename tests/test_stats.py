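import numpy as np
import pandas as pd
import pytest

from pupdyad import (
    ModelSpec,
    PipelineConfig,
    SimParams,
    exclude_poor_retrievers,
    fit_latency_model,
    fit_success_model,
    repeatability_matrix,
    sex_contrast,
    survival_curves_by_trial,
)
from pupdyad.simulate import simulate_features

# Coefficients of R survival::coxph (Efron ties) on the 10-row fixture below,
# frozen as the independent partial-likelihood oracle.
COX_FIXTURE = pd.DataFrame({
    "retrieval_time": [5, 5, 8, 8, 8, 12, 20, 20, 35, 100],
    "success": [1, 1, 1, 0, 1, 1, 1, 0, 1, 0],
    "usv_rate": [3.2, 1.1, 2.5, 0.4, 2.0, 1.8, 0.9, 2.2, 0.5, 3.0],
    "maternal_trial_seq": [1, 2, 1, 3, 2, 4, 1, 2, 3, 4],
})
COX_ORACLE = {"usv_rate": 0.179612625227, "maternal_trial_seq": -0.686327179714}


def _cohort(seed=0, **overrides):
    params = SimParams(seed=seed, **overrides)
    f = simulate_features(params, PipelineConfig())
    return f[~f["self_return"]].reset_index(drop=True)


class TestLatencyModel:
    def test_efron_ties_match_independent_partial_likelihood(self):
        df = COX_FIXTURE.copy()
        df["dam_id"] = "d"
        df["pup_sex"] = ["female", "male"] * 5
        spec = ModelSpec(focal="usv_rate",
                         covariate_factors=(), covariate_continuous=("maternal_trial_seq",))
        res = fit_latency_model(df, spec)
        for term, coef in COX_ORACLE.items():
            assert res.table.loc[term, "estimate"] == pytest.approx(coef, abs=1e-3)

    def test_all_censored_refused(self):
        df = COX_FIXTURE.copy()
        df["success"] = 0
        df["retrieval_time"] = 100.0
        spec = ModelSpec(focal="usv_rate", covariate_factors=(),
                         covariate_continuous=())
        with pytest.raises(ValueError, match="censored"):
            fit_latency_model(df, spec)

    def test_null_effects_center_on_unit_hazard_ratio(self):
        hrs = []
        for seed in range(12):
            f = _cohort(seed=300 + seed, beta_usv_rate=0.0, beta_trial=0.0)
            f["usv_rate"] = f["true_rate"]  # latent rate: no measurement artifact
            res = fit_latency_model(f, ModelSpec(focal="usv_rate"))
            hrs.append(res.exp_estimate("usv_rate"))
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.05)

    def test_row_order_invariance(self):
        f = _cohort(seed=5)
        spec = ModelSpec(focal="usv_rate")
        a = fit_latency_model(f, spec).table
        b = fit_latency_model(f.sample(frac=1.0, random_state=1), spec).table
        pd.testing.assert_frame_equal(a, b, atol=1e-8, rtol=1e-6)

    def test_censoring_bookkeeping(self):
        f = _cohort(seed=6)
        res = fit_latency_model(f, ModelSpec(focal="usv_rate"))
        n_censored = (f.dropna(subset=["usv_rate"])["success"] == 0).sum()
        assert res.n_events + n_censored == res.n_used


class TestSuccessModel:
    def test_recovers_logistic_generator_within_band(self):
        """Success generated directly from a logit model with odds ratio
        0.58 per call/s is recovered by the fit (n = 600)."""
        rng = np.random.default_rng(42)
        ors = []
        for _ in range(20):
            n = 600
            rate = rng.gamma(4.0, 0.5, n)
            seq = rng.integers(1, 7, n)
            sex = rng.choice(["female", "male"], n)
            eta = 2.0 + np.log(0.58) * rate + 0.1 * seq
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            df = pd.DataFrame({
                "dam_id": "d", "pup_sex": sex, "pnd": 7,
                "maternal_trial_seq": seq, "condition": "vehicle",
                "usv_rate": rate, "retrieval_time": 50.0,
                "success": y.astype(int),
            })
            spec = ModelSpec(focal="usv_rate",
                             covariate_factors=("pup_sex",),
                             covariate_continuous=("maternal_trial_seq",))
            ors.append(fit_success_model(df, spec).exp_estimate("usv_rate"))
        assert 0.45 < np.mean(ors) < 0.75
        assert np.mean(ors) == pytest.approx(0.58, abs=0.05)

    def test_constant_success_refused(self):
        f = _cohort(seed=9)
        f["success"] = 1
        f["retrieval_time"] = f["retrieval_time"].clip(upper=99.0)
        with pytest.raises(ValueError, match="constant"):
            fit_success_model(f, ModelSpec(focal="usv_rate"))

    def test_early_retrievals_excluded_for_early_window_focal(self):
        f = _cohort(seed=11)
        res = fit_success_model(f, ModelSpec(focal="n_usv_first_10s"))
        n_early = (f["retrieval_time"] < 10).sum()
        assert res.n_used == len(f) - n_early
        if n_early:
            assert any("before 10 s" in n for n in res.notes)


class TestSurvivalCurves:
    def test_uncensored_closed_form(self):
        df = pd.DataFrame({
            "maternal_trial_seq": 1,
            "retrieval_time": [1.0, 2.0, 3.0],
            "success": 1,
        })
        out = survival_curves_by_trial(df)
        sf = out.set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(1 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_is_flat_at_one(self):
        df = pd.DataFrame({
            "maternal_trial_seq": 1,
            "retrieval_time": [100.0] * 4,
            "success": 0,
        })
        out = survival_curves_by_trial(df)
        assert (out["survival"] == 1.0).all()

    def test_product_limit_with_censoring_matches_hand_computation(self):
        # events at 2 (n=6), 5 (two events, risk 4), 9 (risk 1)
        df = pd.DataFrame({
            "maternal_trial_seq": 2,
            "retrieval_time": [2.0, 4.0, 5.0, 5.0, 7.0, 9.0],
            "success": [1, 0, 1, 1, 0, 1],
        })
        sf = survival_curves_by_trial(df).set_index("time")["survival"]
        assert sf.loc[2.0] == pytest.approx(5 / 6)
        assert sf.loc[5.0] == pytest.approx(5 / 6 * 2 / 4)
        assert sf.loc[9.0] == pytest.approx(0.0)


class TestRepeatability:
    def _features(self, trait_by_unit_day, trait="usv_rate"):
        rows = []
        for (dam, sex), day_vals in trait_by_unit_day.items():
            for day, vals in day_vals.items():
                for v in np.atleast_1d(vals):
                    rows.append({"dam_id": dam, "pup_sex": sex, "pnd": day,
                                 trait: v})
        return pd.DataFrame(rows)

    def test_identical_trait_across_days_gives_unit_correlations(self, rng):
        units = {(f"d{i}", s): {d: rng.uniform(0, 5) + 0 * d for d in (5, 7, 9)}
                 for i in range(6) for s in ("female", "male")}
        for u in units:
            base = units[u][5]
            units[u] = {d: base for d in (5, 7, 9)}
        corr = repeatability_matrix(self._features(units), "usv_rate")
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_independent_noise_gives_near_zero_correlations(self, rng):
        units = {(f"d{i}", s): {d: rng.normal() for d in (5, 7, 9, 11, 13)}
                 for i in range(25) for s in ("female", "male")}
        corr = repeatability_matrix(self._features(units), "usv_rate")
        off = corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.nanmean(np.abs(off)) < 0.2

    def test_aggregation_matches_group_mean_oracle(self):
        df = pd.DataFrame({
            "dam_id": ["a", "a", "a", "a", "b", "b", "c", "c"],
            "pup_sex": ["female"] * 8,
            "pnd": [5, 5, 7, 7, 5, 7, 5, 7],
            "usv_rate": [1.0, 3.0, 2.0, 4.0, 5.0, 6.0, 0.0, 1.0],
        })
        corr = repeatability_matrix(df, "usv_rate")
        # unit means: a: (2,3), b: (5,6), c: (0,1) -> perfectly collinear
        assert corr.loc[5, 7] == pytest.approx(1.0)
        assert corr.attrs["n_pairs"].loc[5, 7] == 3


class TestExclusions:
    def test_poor_retriever_removed_and_boundary_kept(self, config):
        df = pd.DataFrame({
            "dam_id": ["a"] * 4 + ["b"] * 4,
            "success": [1, 0, 0, 0, 1, 1, 0, 0],
        })
        out, excluded = exclude_poor_retrievers(df, config)
        assert excluded == ["a"]          # 1/4 < 50%
        assert set(out["dam_id"]) == {"b"}  # exactly 2/4 is kept

    def test_exclusion_matches_per_dam_tally(self, config, rng):
        dams = rng.choice(list("abcdefgh"), 200)
        succ = rng.integers(0, 2, 200)
        df = pd.DataFrame({"dam_id": dams, "success": succ})
        _, excluded = exclude_poor_retrievers(df, config)
        for dam in "abcdefgh":
            s = succ[dams == dam]
            assert (dam in excluded) == (s.mean() < 0.5)


class TestSexContrast:
    def test_detects_generated_duration_difference(self):
        f = _cohort(seed=21)  # males 8 ms shorter by construction
        est, p = sex_contrast(f, "mean_usv_duration")
        assert est < 0
        assert p < 0.001
        assert est == pytest.approx(-8.0, abs=3.0)

    def test_null_effect_rejection_rate_is_nominal(self):
        rejections = 0
        reps = 120
        for seed in range(reps):
            f = _cohort(seed=5000 + seed, sex_duration_effect=0.0,
                        n_dams=6, days=(7, 9))
            _, p = sex_contrast(f, "mean_usv_duration")
            rejections += p < 0.05
        assert rejections / reps < 0.12

    def test_single_sex_refused(self):
        f = _cohort(seed=2)
        with pytest.raises(ValueError, match="sexes"):
            sex_contrast(f[f["pup_sex"] == "female"], "mean_usv_duration")
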