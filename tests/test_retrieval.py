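import warnings

import numpy as np
import pytest

from pupdyad import (
    apply_start_clamp,
    compute_distance_series,
    estimate_retrieval,
    estimate_trial,
    filter_low_probability,
    flag_self_return,
    smooth_and_reject,
)
from pupdyad.retrieval import (
    MASK_CLAMPED,
    MASK_LOW_LIKELIHOOD,
    MASK_SMOOTH_OUTLIER,
    DistanceSeries,
    QualityWarning,
)
from pupdyad.smoothing import loess_fit, trailing_median
from tests.conftest import make_track


def series(d, fps=30.0, flags=None):
    d = np.asarray(d, dtype=float)
    mask = np.where(np.isnan(d), MASK_LOW_LIKELIHOOD, "kept")
    return DistanceSeries(t=np.arange(len(d)) / fps, d=d, mask=mask,
                          flags=flags or set())


class TestDistanceSeries:
    def test_pixel_distance_scaled_to_mm(self, config):
        track = make_track(config, pup_xy=np.array([[100.0, 100.0]]),
                           nest_xy=(100.0, 327.0))
        ds = compute_distance_series(track, config)
        assert ds.d[0] == pytest.approx(227.0 / 2.27)  # = 100 mm

    def test_frame_missing_when_no_keypoint_passes_cutoff(self, config):
        track = make_track(config, pup_xy=np.array([[10.0, 10.0], [10.0, 10.0]]),
                           nest_xy=(200.0, 200.0),
                           pup_likelihood=np.array([0.05, 0.95]))
        ds = compute_distance_series(track, config)
        assert np.isnan(ds.d[0]) and not np.isnan(ds.d[1])

    def test_matches_mean_then_distance_oracle(self, config, rng):
        """Centroid over passing keypoints, then Euclidean distance."""
        import pandas as pd
        from pupdyad import TrackingTable

        n, parts = 60, ["pup_nose", "pup_centroid", "pup_tailbase"]
        nest = np.array([50.0, 60.0])
        xy = rng.uniform(0, 400, (n, 3, 2))
        lk = rng.uniform(0, 1, (n, 3))
        cols = {}
        for j, p in enumerate(parts):
            cols[(p, "x")] = xy[:, j, 0]
            cols[(p, "y")] = xy[:, j, 1]
            cols[(p, "likelihood")] = lk[:, j]
        cols[("nest", "x")] = np.full(n, nest[0])
        cols[("nest", "y")] = np.full(n, nest[1])
        cols[("nest", "likelihood")] = np.ones(n)
        data = pd.DataFrame(cols)
        data.columns = pd.MultiIndex.from_tuples(data.columns)
        track = TrackingTable(data=data, fps=30.0, px_per_mm=config.px_per_mm,
                              roles={"dam": (), "pup": tuple(parts),
                                     "nest": ("nest",)})
        ds = compute_distance_series(track, config)
        for i in range(n):
            ok = lk[i] >= config.keypoint_p_cutoff
            if not ok.any():
                assert np.isnan(ds.d[i])
                continue
            c = xy[i, ok].mean(axis=0)
            expect = np.hypot(*(c - nest)) / config.px_per_mm
            assert ds.d[i] == pytest.approx(expect)


class TestStartClamp:
    def test_far_start_needs_no_clamp(self, config):
        ds = apply_start_clamp(series(np.full(300, 120.0)), config)
        assert not (ds.mask == MASK_CLAMPED).any()
        assert np.allclose(ds.d, 120.0)

    def test_early_low_frames_clamped_to_bound(self, config):
        d = np.concatenate([np.full(200, 10.0), np.full(400, 120.0)])
        ds = apply_start_clamp(series(d), config)
        med = trailing_median(d, config.rolling_median_window)
        first = int(np.argmax(med > config.start_clamp_distance))
        assert first > 0
        assert (ds.d[:first] == config.start_clamp_distance).all()
        assert (ds.mask[:first] == MASK_CLAMPED).all()
        assert np.allclose(ds.d[first:], d[first:])

    def test_never_above_bound_flags_warning(self, config):
        with pytest.warns(QualityWarning):
            ds = apply_start_clamp(series(np.full(200, 40.0)), config)
        assert "rolling_median_never_above_start_distance" in ds.flags
        assert np.allclose(ds.d, 40.0)  # untouched


class TestLikelihoodFilter:
    def test_frame_below_mean_threshold_discarded(self, config):
        track = make_track(config, pup_xy=np.array([[10.0, 10.0], [10.0, 10.0]]),
                           nest_xy=(300.0, 300.0),
                           pup_likelihood=np.array([0.0045, 1.0]))
        ds = compute_distance_series(track, config)
        out = filter_low_probability(ds, track, config)
        assert np.isnan(out.d[0]) and out.mask[0] == MASK_LOW_LIKELIHOOD
        assert not np.isnan(out.d[1])

    def test_discard_count_matches_brute_force(self, config, rng):
        n = 500
        lk = rng.beta(0.2, 2.0, n)
        track = make_track(config, pup_xy=rng.uniform(0, 400, (n, 2)),
                           nest_xy=(10.0, 10.0), pup_likelihood=lk)
        ds = compute_distance_series(track, config)
        out = filter_low_probability(ds, track, config)
        assert np.isnan(out.d).sum() >= (lk < config.min_mean_pup_likelihood).sum()
        assert ((lk < config.min_mean_pup_likelihood)
                <= np.isnan(out.d)).all()


class TestSmoothReject:
    def test_noiseless_linear_series_untouched(self, config):
        d = np.linspace(300, 20, 400)
        out = smooth_and_reject(series(d), config)
        assert not (out.mask == MASK_SMOOTH_OUTLIER).any()

    def test_single_spike_rejected_exactly(self, config, rng):
        d = 200 + 5 * np.sin(np.arange(600) / 40)
        d[317] += 50.0
        out = smooth_and_reject(series(d), config)
        rejected = np.flatnonzero(out.mask == MASK_SMOOTH_OUTLIER)
        assert rejected.tolist() == [317]

    def test_rejection_set_translation_invariant(self, config, rng):
        d = 150 + rng.normal(0, 6, 500)
        a = smooth_and_reject(series(d), config)
        b = smooth_and_reject(series(d + 77.0), config)
        assert (a.mask == b.mask).all()

    def test_too_few_points_passes_through_with_flag(self, config):
        d = np.full(8, 100.0)
        with pytest.warns(QualityWarning):
            out = smooth_and_reject(series(d), config)
        assert "too_few_points_for_smoothing" in out.flags
        assert np.allclose(out.d, d)


class TestEstimate:
    def test_first_crossing_time(self, config):
        d = np.full(3000, 200.0)
        d[372:] = 10.0  # crossing at frame 372 -> 12.4 s
        est = estimate_retrieval(series(d), config)
        assert est.retrieval_time == pytest.approx(12.4)
        assert est.success == 1 and not est.censored

    def test_never_entering_is_censored_at_trial_end(self, config):
        est = estimate_retrieval(series(np.full(3000, 200.0)), config)
        assert est.retrieval_time == 100.0
        assert est.success == 0 and est.censored

    def test_matches_linear_scan_oracle(self, config, rng):
        for _ in range(50):
            d = rng.uniform(0, 200, 200)
            d[rng.random(200) < 0.3] = np.nan
            est = estimate_retrieval(series(d), config)
            hit = None
            for i, v in enumerate(d):
                if not np.isnan(v) and v <= config.nest_entry_radius:
                    hit = i / 30.0
                    break
            if hit is None:
                assert est.success == 0
            else:
                assert est.retrieval_time == pytest.approx(hit)

    def test_monotone_in_prefix_inflation(self, config, rng):
        """Raising any prefix of the distance trace cannot make the
        detected entry earlier."""
        for _ in range(20):
            d = rng.uniform(10, 120, 300)
            base = estimate_retrieval(series(d), config)
            k = int(rng.integers(1, 300))
            d2 = d.copy()
            d2[:k] = d2[:k] + rng.uniform(0, 80)
            later = estimate_retrieval(series(d2), config)
            assert later.retrieval_time >= base.retrieval_time - 1e-12

    def test_all_missing_yields_censored_with_warning(self, config):
        with pytest.warns(QualityWarning):
            est = estimate_retrieval(series(np.full(100, np.nan)), config)
        assert est.censored and "no_usable_frames" in est.flags


class TestSelfReturn:
    def _entry_track(self, config, dam_path):
        n = 900  # 30 s
        pup = np.tile([400.0, 400.0], (n, 1))
        # pup walks into the nest over the last 6 s
        walk = np.linspace(0, 1, 180)
        pup[-180:] = (1 - walk)[:, None] * np.array([400.0, 400.0]) + \
            walk[:, None] * np.array([50.0, 50.0])
        return make_track(config, pup_xy=pup, nest_xy=(50.0, 50.0),
                          dam_xy=dam_path)

    def test_remote_dam_flags_self_return(self, config):
        n = 900
        track = self._entry_track(config, np.tile([700.0, 50.0], (n, 1)))
        est = estimate_retrieval(compute_distance_series(track, config), config)
        out = flag_self_return(track, est, config)
        assert out.self_return_flag

    def test_nearby_dam_is_a_true_retrieval(self, config):
        n = 900
        pup = np.tile([400.0, 400.0], (n, 1))
        walk = np.linspace(0, 1, 180)
        pup[-180:] = (1 - walk)[:, None] * np.array([400.0, 400.0]) + \
            walk[:, None] * np.array([50.0, 50.0])
        dam = pup + 10.0  # ~6 mm away throughout
        track = make_track(config, pup_xy=pup, nest_xy=(50.0, 50.0), dam_xy=dam)
        est = estimate_retrieval(compute_distance_series(track, config), config)
        out = flag_self_return(track, est, config)
        assert not out.self_return_flag

    def test_flag_matches_min_proximity_oracle(self, config, rng):
        for _ in range(15):
            n = 600
            pup = rng.uniform(0, 500, (n, 2))
            pup[-60:] = [50.0, 50.0]  # ends in the nest
            dam = rng.uniform(0, 900, (n, 2))
            track = make_track(config, pup_xy=pup, nest_xy=(50.0, 50.0),
                               dam_xy=dam)
            ds = compute_distance_series(track, config)
            est = estimate_retrieval(ds, config)
            assert est.success == 1
            out = flag_self_return(track, est, config)
            t = track.times()
            win = (t >= est.retrieval_time - config.self_return_lookback) & (
                t <= est.retrieval_time)
            prox = np.hypot(*(dam - pup).T) / config.px_per_mm
            assert out.self_return_flag == (prox[win].min()
                                            > config.self_return_proximity)


def test_full_chain_on_degenerate_track_warns_not_raises(config):
    track = make_track(config, pup_xy=np.zeros((120, 2)), nest_xy=(500.0, 500.0),
                       pup_likelihood=np.zeros(120))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est, ds = estimate_trial(track, config)
    assert est.censored and est.success == 0
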