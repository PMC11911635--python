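import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenocage import (
    HomecageSimSpec,
    REGISTRY,
    component_percentile,
    compute_phenotype_vector,
    empirical_percentile_threshold,
    fit_log2_mixture,
    gaussian_intersection,
    habituation_index,
    hourly_activity_profile,
    sample_shelter_visits,
    simulate_homecage_events,
    switch_delta,
)
from phenocage.geometry import LightCycle
from phenocage.spontaneous_params import HourlyActivityProfile, PhenotypeConfig
from phenocage.tracking_events import EventLog


def grid_intersection(c1, c2, n=200001):
    """Dense-grid sign-change oracle for the weighted-density crossing."""
    w1, m1, s1 = c1
    w2, m2, s2 = c2
    x = np.linspace(m1, m2, n)
    f = w1 * stats.norm.pdf(x, m1, s1) - w2 * stats.norm.pdf(x, m2, s2)
    sign = np.sign(f)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if idx.size == 0:
        return None
    return 0.5 * (x[idx[0]] + x[idx[0] + 1])


class TestMixtureFit:
    def test_recovers_three_component_means(self):
        mix_mu = (4.0, 7.0, 11.0)
        rng = np.random.default_rng(0)
        comp = rng.choice(3, size=5000, p=[0.3, 0.4, 0.3])
        x = rng.normal(np.asarray(mix_mu)[comp], 0.5)
        fit = fit_log2_mixture(np.power(2.0, x), k=3, seed=1)
        assert fit.converged and not fit.missing
        assert np.all(np.abs(fit.means - np.asarray(mix_mu)) < 0.15)
        assert np.all(np.diff(fit.means) > 0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_log_likelihood_never_decreases(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(3, 0.5, 300), rng.normal(7, 0.7, 300)])
        fit = fit_log2_mixture(np.power(2.0, x), k=2, seed=5)
        assert fit.ll_trace is not None and len(fit.ll_trace) > 1
        assert np.all(np.diff(fit.ll_trace) > -1e-7)

    def test_constant_input_is_missing(self):
        fit = fit_log2_mixture(np.full(100, 8.0), k=3)
        assert fit.missing and not fit.converged

    def test_too_few_points_flagged_missing(self):
        fit = fit_log2_mixture(np.arange(1, 11, dtype=float), k=3, min_points=30)
        assert fit.missing

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_log2_mixture(np.array([1.0, -2.0, 3.0] * 20), k=2)

    def test_agrees_with_reference_em(self):
        """Cross-check against an independent EM implementation."""
        sklearn_gm = pytest.importorskip("sklearn.mixture").GaussianMixture
        rng = np.random.default_rng(11)
        comp = rng.choice(2, size=2000, p=[0.6, 0.4])
        x = rng.normal(np.array([2.0, 6.0])[comp], np.array([0.5, 0.8])[comp])
        fit = fit_log2_mixture(np.power(2.0, x), k=2, seed=0)
        gm = sklearn_gm(n_components=2, n_init=5, tol=1e-8, random_state=0,
                        max_iter=500).fit(x[:, None])
        order = np.argsort(gm.means_[:, 0])
        np.testing.assert_allclose(fit.means, gm.means_[order, 0], atol=0.02)
        np.testing.assert_allclose(fit.weights, gm.weights_[order], atol=0.02)
        np.testing.assert_allclose(
            fit.sds, np.sqrt(gm.covariances_[order, 0, 0]), atol=0.02
        )


class TestIntersection:
    def test_symmetric_case_is_midpoint(self):
        res = gaussian_intersection((0.5, 6.0, 1.0), (0.5, 10.0, 1.0))
        assert res.threshold == pytest.approx(8.0, abs=1e-12)
        assert not res.fallback

    @pytest.mark.parametrize(
        "c1,c2",
        [
            ((0.7, 6.0, 1.0), (0.3, 10.0, 1.0)),
            ((0.4, 7.0, 0.5), (0.3, 11.0, 0.5)),
            ((0.5, 2.0, 0.4), (0.5, 5.0, 1.2)),  # unequal sds
            ((0.2, 0.0, 0.8), (0.8, 3.0, 0.3)),
        ],
    )
    def test_matches_grid_oracle(self, c1, c2):
        oracle = grid_intersection(c1, c2)
        res = gaussian_intersection(c1, c2)
        assert oracle is not None and not res.fallback
        assert res.threshold == pytest.approx(oracle, abs=1e-3)

    def test_no_crossing_falls_back_to_weighted_midpoint(self):
        # overwhelming first component: its density dominates everywhere between
        c1, c2 = (0.999, 5.0, 3.0), (0.001, 6.0, 0.01)
        res = gaussian_intersection(c1, c2)
        if res.fallback:
            expect = (0.999 * 5.0 + 0.001 * 6.0) / 1.0
            assert res.threshold == pytest.approx(expect)
        else:  # if a crossing exists the grid oracle must agree
            assert grid_intersection(c1, c2) == pytest.approx(res.threshold, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gaussian_intersection((0.5, 6.0, -1.0), (0.5, 10.0, 1.0))
        with pytest.raises(ValueError):
            gaussian_intersection((0.5, 10.0, 1.0), (0.5, 6.0, 1.0))


class TestPercentiles:
    def test_gaussian_90th(self):
        # bisection oracle on the Gaussian CDF
        lo, hi = 2.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if stats.norm.cdf(mid, 2.0, 1.0) < 0.9:
                lo = mid
            else:
                hi = mid
        assert component_percentile((2.0, 1.0), 0.9) == pytest.approx(lo, abs=1e-9)
        assert component_percentile((2.0, 1.0), 0.9) == pytest.approx(3.2816, abs=1e-4)

    def test_median_is_mean_and_sd_linearity(self):
        assert component_percentile((5.0, 2.0), 0.5) == pytest.approx(5.0)
        d1 = component_percentile((0.0, 1.0), 0.9)
        d2 = component_percentile((0.0, 2.0), 0.9)
        assert d2 == pytest.approx(2 * d1)

    def test_out_of_range_q(self):
        with pytest.raises(ValueError):
            component_percentile((0.0, 1.0), 1.5)

    def test_nearest_rank_on_1_to_100(self):
        assert empirical_percentile_threshold(np.arange(1.0, 101.0)) == 90.0

    def test_constant_durations(self):
        assert empirical_percentile_threshold(np.full(50, 7.0)) == 7.0

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(0.1, 1e4), min_size=10, max_size=60),
        st.floats(0.1, 10.0),
    )
    def test_scale_equivariance(self, xs, alpha):
        xs = np.asarray(xs)
        t1 = empirical_percentile_threshold(alpha * xs)
        t2 = alpha * empirical_percentile_threshold(xs)
        assert t1 == pytest.approx(t2, rel=1e-9)


def profile_from_hours(dark_hours: list[list[float]],
                       light_hours: list[list[float]]) -> HourlyActivityProfile:
    rows = []
    for pi, hours in enumerate(dark_hours, start=1):
        for h, v in enumerate(hours, start=1):
            rows.append(dict(phase="dark", phase_index=pi, hour=h,
                             start_s=0.0, activity_s=v, complete=True))
    for pi, hours in enumerate(light_hours, start=1):
        for h, v in enumerate(hours, start=1):
            rows.append(dict(phase="light", phase_index=pi, hour=h,
                             start_s=0.0, activity_s=v, complete=True))
    return HourlyActivityProfile(pd.DataFrame(rows))


class TestActivityIndices:
    def test_habituation_identity(self):
        hrs = [[100.0] * 12, [80.0] * 12, [100.0] * 12]
        prof = profile_from_hours(hrs, [[10.0] * 12] * 3)
        assert habituation_index(prof) == 1.0

    def test_habituation_ratio_and_scale_invariance(self):
        hrs = [[100.0] * 12, [80.0] * 12, [50.0] * 12]
        prof = profile_from_hours(hrs, [[10.0] * 12] * 3)
        assert habituation_index(prof) == pytest.approx(0.5)
        doubled = profile_from_hours([[2 * v for v in h] for h in hrs],
                                     [[10.0] * 12] * 3)
        assert habituation_index(doubled) == pytest.approx(0.5)

    def test_zero_first_phase_is_missing(self):
        prof = profile_from_hours([[0.0] * 12, [5.0] * 12, [5.0] * 12],
                                  [[1.0] * 12] * 3)
        assert np.isnan(habituation_index(prof))

    def test_constant_profile_gives_zero_deltas(self):
        prof = profile_from_hours([[100.0] * 12] * 3, [[100.0] * 12] * 3)
        for sw in ("to_dark", "to_light"):
            for win in ("anticipation", "response"):
                assert switch_delta(prof, sw, win, day=3) == 0.0

    def test_anticipation_arithmetic(self):
        # light phase 2: hours 8-10 at 100 s/h, hours 11-12 at 150 and 170
        light2 = [100.0] * 10 + [150.0, 170.0]
        prof = profile_from_hours([[50.0] * 12] * 3,
                                  [[100.0] * 12, light2, [100.0] * 12])
        assert switch_delta(prof, "to_dark", "anticipation", day=3) == pytest.approx(60.0)

    def test_response_uses_original_phase_baseline(self):
        dark3 = [200.0] * 12
        prof = profile_from_hours([[50.0] * 12, [50.0] * 12, dark3],
                                  [[100.0] * 12] * 3)
        # response to dark on day 3: dark3 hours 1-2 (200) minus light2 hours 8-10 (100)
        assert switch_delta(prof, "to_dark", "response", day=3) == pytest.approx(100.0)

    def test_modulated_generator_shows_positive_dark_response(self):
        """A +50% response-to-dark rate factor yields a positive group-mean
        response delta, with phase base rates held equal so only the
        modulation can produce the effect."""
        import math

        hits = 0
        n, group = 40, 3
        for rep in range(n):
            deltas = []
            for j in range(group):
                spec = HomecageSimSpec(
                    seed=5000 + rep * group + j, duration_days=2, sample_rate=5.0,
                    activity_bout_rate_per_phase={"dark": 30.0, "light": 30.0},
                    activity_bout_duration=(math.log(20.0), 0.3),
                    shelter_visit_rate_per_phase={"dark": 0.3, "light": 0.3},
                    anticipation_response_modulation={
                        "to_dark": {"anticipation": 1.0, "response": 1.5},
                        "to_light": {"anticipation": 1.0, "response": 1.0},
                    },
                )
                events = simulate_homecage_events(spec)
                prof = hourly_activity_profile(events, spec.lightcycle, 2 * 86400.0)
                deltas.append(switch_delta(prof, "to_dark", "response", day=2))
            if np.mean(deltas) > 0:
                hits += 1
        assert hits >= 0.95 * n


class TestPhenotypeVector:
    def test_exactly_twenty_named_parameters(self, three_day_spec):
        events = simulate_homecage_events(three_day_spec)
        vec = compute_phenotype_vector(events, three_day_spec.lightcycle)
        assert len(vec) == 20
        assert list(vec.values) == list(REGISTRY)

    def test_deterministic(self, three_day_spec):
        events = simulate_homecage_events(three_day_spec)
        v1 = compute_phenotype_vector(events, three_day_spec.lightcycle)
        v2 = compute_phenotype_vector(events, three_day_spec.lightcycle)
        pd.testing.assert_frame_equal(v1.to_frame(), v2.to_frame())

    def test_zero_activity_trace(self):
        """No bouts and no shelter visits: totals 0, mixture thresholds missing."""
        spec = HomecageSimSpec(
            seed=1, duration_days=3, sample_rate=5.0,
            activity_bout_rate_per_phase={"dark": 0.0, "light": 0.0},
            shelter_visit_rate_per_phase={"dark": 0.0, "light": 0.0},
        )
        events = simulate_homecage_events(spec)
        vec = compute_phenotype_vector(events, spec.lightcycle)
        assert vec["activity_total_dark"].value == 0.0
        assert vec["activity_total_light"].value == 0.0
        assert vec["movement_threshold_long"].missing
        assert vec["shelter_threshold_long"].missing
        assert vec["shelter_threshold_short"].missing
        assert vec["arrest_threshold_long"].missing  # a single arrest spans the trace
        assert len(vec) == 20

    def test_long_threshold_close_to_analytic_intersection(self, three_day_spec):
        mix = three_day_spec.shelter_visit_log2_mixture
        truth = gaussian_intersection(
            (mix.weights[1], mix.means[1], mix.sds[1]),
            (mix.weights[2], mix.means[2], mix.sds[2]),
        ).threshold
        errs = []
        for rep in range(5):
            spec = HomecageSimSpec(seed=300 + rep, duration_days=3, sample_rate=5.0)
            events = simulate_homecage_events(spec)
            vec = compute_phenotype_vector(events, spec.lightcycle)
            assert not vec["shelter_threshold_long"].missing
            errs.append(abs(vec["shelter_threshold_long"].value - truth))
        assert np.median(errs) < 0.3

    def test_short_below_long_threshold(self, three_day_spec):
        events = simulate_homecage_events(three_day_spec)
        vec = compute_phenotype_vector(events, three_day_spec.lightcycle)
        assert vec["shelter_threshold_short"].value < vec["shelter_threshold_long"].value

    def test_long_plus_nonlong_visits_cover_shelter_time(self, three_day_spec):
        events = simulate_homecage_events(three_day_spec)
        vec = compute_phenotype_vector(events, three_day_spec.lightcycle)
        visits = events.of_kind("shelter_visit")
        day3 = visits[(visits["start"] >= 2 * 86400.0) & (visits["start"] < 3 * 86400.0)]
        dur = (day3["end"] - day3["start"]).to_numpy()
        long_thr = vec["shelter_threshold_long"].value
        long_sum = dur[np.log2(dur) > long_thr].sum()
        nonlong_sum = dur[np.log2(dur) <= long_thr].sum()
        assert vec["shelter_cum_long_duration"].value == pytest.approx(long_sum, rel=1e-9)
        assert long_sum + nonlong_sum == pytest.approx(dur.sum())

    def test_strict_mode_needs_three_dark_phases(self, day_spec):
        events = simulate_homecage_events(day_spec)
        with pytest.raises(ValueError):
            compute_phenotype_vector(events, day_spec.lightcycle)
        vec = compute_phenotype_vector(events, day_spec.lightcycle, strict=False)
        assert len(vec) == 20
        assert vec["habituation_index_dark"].missing
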