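import numpy as np
import pytest
from scipy.stats import binom

import strandmort as sm
from strandmort.heligman_pollard import (DeathsAtAge, PriorSpec, deaths_at_age,
                                         expected_unique_fraction)
from strandmort.life_tables import AgeSample


def toy_params(**overrides):
    base = dict(A=0.05, B=0.5, C=1.0, D=0.04, E=1.5, F=3.0,
                G=0.001, H=1.2, I=0.01)
    base.update(overrides)
    return sm.AHPParams(**base)


class TestCurve:
    def test_infant_term_exponent_one(self):
        # (x + B)^C = 1 at x = 0.9, B = 0.1, C = 1 -> q equals A
        p = toy_params(A=0.05, B=0.1, C=1.0, D=0.0, E=1.0, G=0.0, H=1.0, I=0.0)
        sched = sm.ahp_qx(p, [0.9])
        assert sched.total[0] == pytest.approx(0.05)

    def test_hump_height_at_its_centre(self):
        sched = sm.ahp_qx(toy_params(D=0.07, I=0.02), [3.0])
        assert sched.components["hump"][0] == pytest.approx(0.09)

    def test_adult_term_saturates(self):
        # the logistic G H^x / (1 + G H^x) -> 1 as G grows
        p = toy_params(A=0.0, B=0.5, C=1.0, D=0.0, I=0.0, G=1e9, H=1.0)
        assert sm.ahp_qx(p, [5.0], strict=False).components["adult"][0] \
            == pytest.approx(1.0, abs=1e-8)

    def test_age_zero_is_finite(self):
        sched = sm.ahp_qx(toy_params(), [0.0])
        assert np.isfinite(sched.total[0])

    def test_strict_rejects_probability_above_one(self):
        p = toy_params(I=0.8, G=1.0, H=1.3)
        with pytest.raises(ValueError):
            sm.ahp_qx(p, np.arange(1, 30))

    def test_unadapted_hp_drops_baseline(self):
        p = toy_params(I=0.05)
        at_f = sm.hp_qx(p, [3.0]).components["hump"][0]
        assert at_f == pytest.approx(p.D)


class TestDecompose:
    def test_no_hump_means_all_natural(self):
        parts = sm.decompose(toy_params(D=0.0, I=0.0), np.arange(1, 20))
        assert np.all(parts["anthropogenic"] == 0)
        np.testing.assert_allclose(parts["total"], parts["natural"])

    def test_components_sum_to_total(self):
        parts = sm.decompose(toy_params(), np.arange(0, 25))
        np.testing.assert_allclose(
            parts["natural"] + parts["anthropogenic"], parts["total"],
            atol=1e-12)


class TestPriors:
    def test_collapsed_bounds_pin_draws(self):
        bounds = {k: (v, v + 1e-9) for k, v in
                  zip(sm.AHP_PARAM_NAMES, toy_params().as_array())}
        draws = sm.draw_priors(PriorSpec(bounds=bounds, n_draws=50), seed=0)
        np.testing.assert_allclose(
            draws, np.tile(toy_params().as_array(), (50, 1)), atol=1e-8)

    def test_seed_reproducibility(self):
        spec = PriorSpec(n_draws=100)
        np.testing.assert_array_equal(sm.draw_priors(spec, seed=4),
                                      sm.draw_priors(spec, seed=4))

    def test_uniform_moments(self):
        spec = PriorSpec(n_draws=100_000)
        draws = sm.draw_priors(spec, seed=1)
        lo, hi = spec.arrays()
        se = (hi - lo) / np.sqrt(12 * spec.n_draws)
        assert np.all(np.abs(draws.mean(axis=0) - (lo + hi) / 2) <= 3 * se)

    def test_invalid_bounds_rejected(self):
        bad = dict(PriorSpec().bounds)
        bad["A"] = (0.5, 0.1)
        with pytest.raises(ValueError):
            PriorSpec(bounds=bad)


class TestLikelihood:
    def toy_data(self):
        return DeathsAtAge(ages=np.arange(5, dtype=float),
                           deaths=np.array([30., 20., 10., 8., 12.]),
                           at_risk=np.array([80., 50., 30., 20., 12.]))

    def test_matches_binomial_pmf_product(self):
        from scipy.special import gammaln
        data = self.toy_data()
        p = toy_params()
        q = sm.ahp_qx(p, data.ages).total
        # log of the product of binomial pmfs, with the parameter-free
        # binomial coefficients subtracted back out
        full = binom.logpmf(data.deaths, data.at_risk, q).sum()
        coeffs = np.sum(gammaln(data.at_risk + 1) - gammaln(data.deaths + 1)
                        - gammaln(data.at_risk - data.deaths + 1))
        assert sm.ahp_loglik(p, data) == pytest.approx(full - coeffs, abs=1e-10)

    def test_saturated_rates_maximise(self):
        # any parameter curve scores below the saturated q = M/S fit
        data = self.toy_data()
        q_hat = data.deaths / data.at_risk
        surv = data.at_risk - data.deaths
        open_classes = surv > 0
        saturated = np.sum(data.deaths * np.log(q_hat)) + np.sum(
            surv[open_classes] * np.log1p(-q_hat[open_classes]))
        assert sm.ahp_loglik(toy_params(), data) <= saturated

    def test_invalid_curve_gets_minus_infinity(self):
        data = self.toy_data()
        assert sm.ahp_loglik(toy_params(I=0.9, G=1.0), data) == -np.inf

    def test_at_risk_from_cohort(self, small_sample):
        data = deaths_at_age(small_sample)
        assert data.at_risk[0] == len(small_sample)
        assert np.all(np.diff(data.at_risk) <= 0)
        assert data.deaths.sum() == len(small_sample)


class TestFit:
    def fit_small(self, **kwargs):
        samp = sm.simulate_scenario(sm.ScenarioSpec(seed=1))
        return sm.fit_ahp(samp, seed=1, **kwargs)

    def test_posterior_structure(self):
        post = self.fit_small()
        assert post.params.shape == (500, 9)
        assert post.weights.sum() == pytest.approx(1.0)
        assert np.all(post.weights >= 0)
        # resampled rows all come from the weighted pool
        pool_set = {tuple(r) for r in post.pool}
        assert all(tuple(r) in pool_set for r in post.params[:20])

    def test_stopping_diagnostic_reported(self):
        post = self.fit_small()
        assert 0 < post.unique_fraction <= 1
        assert len(post.unique_fraction_trace) >= 1
        if post.n_imis_used < 10:
            assert post.unique_fraction >= sm.IMIS_STOP_FRACTION

    def test_determinism(self):
        a, b = self.fit_small(), self.fit_small()
        np.testing.assert_array_equal(a.params, b.params)

    def test_single_row_resample(self):
        post = self.fit_small(n_resample=1)
        assert post.params.shape == (1, 9)

    def test_incompatible_priors_raise(self):
        bounds = dict(PriorSpec().bounds)
        bounds["I"] = (0.995, 0.999)  # hump baseline forces q > 1 everywhere
        samp = sm.simulate_scenario(sm.ScenarioSpec(seed=1))
        with pytest.raises(ValueError, match="priors incompatible"):
            sm.fit_ahp(samp, PriorSpec(bounds=bounds, n_draws=200), seed=0)

    def test_hump_location_recovered(self):
        spec = sm.ScenarioSpec(n_natural=2200, n_bycatch=800,
                               bycatch_mean_age=3.0, bycatch_sd=1.5, seed=2)
        post = sm.fit_ahp(sm.simulate_scenario(spec), seed=2)
        peak = sm.hump_peak_age(post, np.arange(0, 15.01, 0.25))
        assert abs(peak - 3.0) <= 2.0

    def test_nests_siler_when_hump_removed(self, siler_truth):
        # with the hump pinned at zero the aHP total mortality must agree
        # with an independently fitted Siler curve on Siler-generated data,
        # over the ages the data actually support (the two forms extrapolate
        # differently once almost nobody is left at risk)
        spec = sm.ScenarioSpec(siler=siler_truth, n_natural=2000, n_bycatch=0,
                               max_age=30, seed=4)
        samp = sm.simulate_natural(spec)
        post = sm.fit_ahp(samp, seed=4, fixed={"D": 0.0, "I": 0.0})
        p_siler, _ = sm.fit_siler(samp, max_age=30, seed=4)
        counts = samp.binned_counts(max_age=30)
        at_risk = np.cumsum(counts[::-1])[::-1]
        ages = np.arange(1, 31)[at_risk[1:] >= 30]
        q_siler = sm.siler_qx(p_siler, ages)
        bands = sm.predict_ahp(post, ages)
        inside = (q_siler >= bands.total_lower.to_numpy()) \
            & (q_siler <= bands.total_upper.to_numpy())
        assert inside.mean() >= 0.6


class TestPredict:
    def test_degenerate_posterior_has_zero_width(self):
        params = np.tile(toy_params().as_array(), (20, 1))
        post = sm.PosteriorSample(params=params, weights=np.full(20, 0.05),
                                  unique_fraction=1.0, n_imis_used=0, seed=0)
        bands = sm.predict_ahp(post, np.arange(1, 10))
        np.testing.assert_allclose(bands.total_lower, bands.total_upper)

    def test_zero_level_collapses_to_median(self):
        post = self.small_posterior()
        bands = sm.predict_ahp(post, np.arange(1, 10), level=0.0)
        np.testing.assert_allclose(bands.total_lower, bands.total_median)
        np.testing.assert_allclose(bands.total_upper, bands.total_median)

    def small_posterior(self):
        rng = np.random.default_rng(0)
        params = np.tile(toy_params().as_array(), (50, 1))
        params[:, 0] *= rng.uniform(0.9, 1.1, 50)
        return sm.PosteriorSample(params=params, weights=np.full(50, 0.02),
                                  unique_fraction=1.0, n_imis_used=0, seed=0)

    def test_band_width_shrinks_with_sample_size(self, ahp_truth):
        q_true = sm.ahp_qx(ahp_truth, np.arange(31)).total
        widths = {}
        for n in (300, 3000):
            samp = sm.simulate_from_qx(q_true, n, seed=6)
            post = sm.fit_ahp(samp, seed=6)
            bands = sm.predict_ahp(post, np.arange(1, 30))
            widths[n] = float(np.mean(bands.total_upper - bands.total_lower))
        assert widths[3000] < widths[300]


def test_expected_unique_fraction_closed_form():
    # uniform weights over n points, resample of k: 1 - (1 - 1/n)^k per point
    w = np.full(10, 0.1)
    expected = 10 * (1 - (1 - 0.1) ** 5) / 5
    assert expected_unique_fraction(w, 5) == pytest.approx(expected)
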