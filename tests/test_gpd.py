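"""Distribution functions, exceedance construction and the three estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from yieldtail import (FitError, GPDParams, fit_ml, fit_moment, fit_pwm,
                       gpd_cdf, gpd_loglik, gpd_pdf, gpd_quantile, gpd_sample,
                       select_exceedances)
from conftest import make_exceedances


# ---------------------------------------------------------------------------
# Distribution functions
# ---------------------------------------------------------------------------

class TestDistribution:
    def test_cdf_at_zero_and_endpoint(self):
        assert gpd_cdf(0.0, GPDParams(-0.11, 0.76)) == 0.0
        assert gpd_cdf(0.0, GPDParams(0.5, 2.0)) == 0.0
        # support boundary: endpoint of gamma=-0.5, sigma=1 is 2
        assert gpd_cdf(2.0, GPDParams(-0.5, 1.0)) == pytest.approx(1.0, abs=1e-14)
        assert gpd_cdf(5.0, GPDParams(-0.5, 1.0)) == 1.0

    def test_negative_excess_rejected(self):
        with pytest.raises(ValueError):
            gpd_cdf(-0.1, GPDParams(0.0, 1.0))
        with pytest.raises(ValueError):
            gpd_pdf(-1.0, GPDParams(0.0, 1.0))
        with pytest.raises(ValueError):
            gpd_quantile(1.0, GPDParams(0.0, 1.0))
        with pytest.raises(ValueError):
            gpd_quantile(-0.2, GPDParams(0.0, 1.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GPDParams(0.1, 0.0)
        with pytest.raises(ValueError):
            GPDParams(0.1, -1.0)

    def test_cdf_matches_quadrature(self):
        # integrate the density and compare with the closed-form CDF
        p = GPDParams(-0.11, 0.76)
        val, err = integrate.quad(lambda y: gpd_pdf(y, p), 0.0, 0.76,
                                  epsabs=1e-13, epsrel=1e-13)
        assert abs(val - gpd_cdf(0.76, p)) <= 1e-10

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        gamma=st.floats(-0.9, 0.9),
        sigma=st.floats(0.05, 20.0),
        p=st.floats(0.0, 0.999),
    )
    def test_quantile_roundtrip(self, gamma, sigma, p):
        params = GPDParams(gamma, sigma)
        assert abs(gpd_cdf(gpd_quantile(p, params), params) - p) <= 1e-10

    def test_continuity_in_gamma_at_zero(self):
        for y in (0.1, 0.5, 1.0, 3.0, 10.0):
            ref = gpd_cdf(y, GPDParams(0.0, 2.0))
            for g in (1e-8, -1e-8):
                assert abs(gpd_cdf(y, GPDParams(g, 2.0)) - ref) <= 1e-6

    def test_exponential_quantile_closed_form(self):
        # gamma = 0: quantile of 1 - exp(-y/sigma) at p = 1 - 1/e is sigma
        assert gpd_quantile(1.0 - math.exp(-1.0), GPDParams(0.0, 2.0)) == pytest.approx(2.0, abs=1e-12)

    def test_sampling_matches_cdf(self):
        # empirical CDF of inverse-transform draws within the DKW band
        params = GPDParams(-0.2, 1.0)
        n = 100_000
        draws = gpd_sample(params, n, np.random.default_rng(42))
        xs = np.sort(draws)
        ecdf = np.arange(1, n + 1) / n
        sup = np.max(np.abs(ecdf - gpd_cdf(xs, params)))
        eps = math.sqrt(math.log(2 / 1e-4) / (2 * n))  # alpha = 1e-4
        assert sup <= eps

    def test_sampling_reproducible(self):
        params = GPDParams(-0.11, 0.76)
        a = gpd_sample(params, 100, np.random.default_rng(7))
        b = gpd_sample(params, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# Exceedance selection
# ---------------------------------------------------------------------------

class TestSelectExceedances:
    def test_order_statistics_by_hand(self):
        exc = select_exceedances(np.arange(1.0, 11.0), 3)
        assert exc.threshold == 7.0
        assert sorted(exc.excesses) == [1.0, 2.0, 3.0]
        assert exc.t0 == 10.0 and exc.n == 10 and exc.k == 3

    def test_k_equals_n_minus_one_threshold_is_minimum(self):
        x = np.array([3.1, 0.7, 5.5, 2.2, 9.9])
        exc = select_exceedances(x, 4)
        assert exc.threshold == 0.7

    def test_k_out_of_range(self):
        x = np.arange(1.0, 11.0)
        for k in (0, 10, 11):
            with pytest.raises(ValueError):
                select_exceedances(x, k)

    def test_tie_at_threshold_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            select_exceedances(np.array([1.0, 2.0, 2.0, 3.0]), 2)

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(123)
        x = rng.normal(8.0, 2.0, 200)  # continuous: no exact ties
        for k in (1, 5, 50, 199):
            exc = select_exceedances(x, k)
            srt = sorted(x)
            assert exc.threshold == srt[-(k + 1)]
            np.testing.assert_allclose(
                np.sort(exc.excesses), np.array(srt[-k:]) - srt[-(k + 1)])


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

class TestFitML:
    def test_parameter_recovery(self):
        exc = make_exceedances(-0.2, 1.0, 5000, seed_or_rng=11)
        fit = fit_ml(exc)
        assert fit.params.gamma == pytest.approx(-0.2, abs=0.05)
        assert fit.params.sigma == pytest.approx(1.0, abs=0.05)
        assert fit.converged
        assert fit.loglik == pytest.approx(
            gpd_loglik(exc.excesses, fit.params.gamma, fit.params.sigma))

    def test_beats_grid_search_oracle(self):
        # exhaustive 200x200 search over (gamma, log sigma) never beats ML
        rng = np.random.default_rng(17)
        for gamma in (-0.3, 0.0, 0.5):
            k = int(rng.integers(50, 301))
            exc = make_exceedances(gamma, 1.0, k, seed_or_rng=rng)
            fit = fit_ml(exc)
            y = exc.excesses
            gammas = np.linspace(-0.95, 1.5, 200)
            logsig = np.linspace(np.log(y.mean()) - 2, np.log(y.mean()) + 2, 200)
            grid_best = max(
                gpd_loglik(y, g, math.exp(ls)) for g in gammas for ls in logsig)
            assert fit.loglik >= grid_best - 1e-6

    def test_exponential_submodel_closed_form(self):
        # gamma = 0 truth: shape goes to 0 and scale to the sample mean
        exc = make_exceedances(0.0, 1.5, 5000, seed_or_rng=3)
        fit = fit_ml(exc)
        assert abs(fit.params.gamma) < 0.05
        assert fit.params.sigma == pytest.approx(float(exc.excesses.mean()), rel=0.05)

    def test_scale_equivariance(self):
        exc = make_exceedances(-0.25, 1.0, 400, seed_or_rng=5)
        fit = fit_ml(exc)
        c = 3.7
        scaled = make_exceedances(-0.25, 1.0, 400, seed_or_rng=5)
        scaled = type(scaled)(
            threshold=scaled.threshold,
            excesses=np.sort(scaled.excesses * c),
            k=scaled.k, n=scaled.n,
            t0=scaled.threshold + float(scaled.excesses.max() * c))
        fit_c = fit_ml(scaled)
        assert fit_c.params.gamma == pytest.approx(fit.params.gamma, abs=1e-4)
        assert fit_c.params.sigma == pytest.approx(c * fit.params.sigma, rel=1e-4)

    def test_agrees_with_independent_optimizer(self):
        # scipy's own GPD fitter as an independent route to the same optimum
        exc = make_exceedances(-0.15, 0.8, 800, seed_or_rng=9)
        fit = fit_ml(exc)
        c, loc, scale = stats.genpareto.fit(exc.excesses, floc=0.0)
        assert fit.loglik >= gpd_loglik(exc.excesses, c, scale) - 1e-6
        assert fit.params.gamma == pytest.approx(c, abs=1e-3)

    def test_degenerate_and_tiny_inputs_rejected(self):
        exc = make_exceedances(-0.2, 1.0, 10, seed_or_rng=1)
        degenerate = type(exc)(threshold=1.0, excesses=np.full(10, 2.0),
                               k=10, n=60, t0=3.0)
        with pytest.raises(FitError):
            fit_ml(degenerate)

    def test_warns_outside_regular_regime(self):
        # uniform excesses correspond to gamma = -1: no Wald theory
        rng = np.random.default_rng(8)
        y = np.sort(rng.random(300))
        exc = make_exceedances(-0.2, 1.0, 300, seed_or_rng=1)
        uniform = type(exc)(threshold=5.0, excesses=y, k=300, n=1800,
                            t0=5.0 + float(y.max()))
        with pytest.warns(UserWarning, match="-1/2"):
            fit = fit_ml(uniform)
        assert fit.params.gamma < -0.5
        assert fit.cov is None


# ---------------------------------------------------------------------------
# Moment and PWM estimators
# ---------------------------------------------------------------------------

class TestSemiParametricEstimators:
    def test_pwm_b0_is_mean_of_excesses(self):
        # at gamma=0, sigma = 2*b0*b1/(b0-2b1) reduces to b0 = mean when
        # b1 = b0/4; check the b0 identity through the exponential submodel
        exc = make_exceedances(0.0, 1.0, 5000, seed_or_rng=2)
        y = np.sort(exc.excesses)
        k = y.size
        b0 = y.mean()
        b1 = float((y * (k - 1 - np.arange(k)) / (k - 1)).mean())
        params = fit_pwm(exc)
        # reconstruct b0 from the estimator's defining equations
        assert 2.0 * b0 * b1 / (b0 - 2 * b1) == pytest.approx(params.sigma)
        assert 2.0 - b0 / (b0 - 2 * b1) == pytest.approx(params.gamma)

    def test_pwm_parameter_recovery(self):
        exc = make_exceedances(-0.11, 0.76, 10_000, seed_or_rng=13, threshold=10.69)
        params = fit_pwm(exc)
        assert params.gamma == pytest.approx(-0.11, abs=0.05)
        assert params.sigma == pytest.approx(0.76, abs=0.05)

    def test_moment_close_to_ml(self):
        # the two estimators agree within twice the ML standard error in
        # at least 90% of replicates
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            exc = make_exceedances(-0.11, 0.76, 2000, seed_or_rng=rng,
                                   threshold=10.69)
            ml = fit_ml(exc)
            mom = fit_moment(exc)
            se = (1 + ml.params.gamma) / math.sqrt(2000)
            if abs(mom.gamma - ml.params.gamma) < 2 * se:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_small_k_rejected(self):
        exc = make_exceedances(-0.2, 1.0, 3, seed_or_rng=1)
        with pytest.raises(FitError):
            fit_moment(exc)
        with pytest.raises(FitError):
            fit_pwm(exc)
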