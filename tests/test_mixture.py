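"""Symmetric three-component Z-score mixture: likelihood, fit, bootstrap."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.base import clone

from pleioaudit.mixture import (
    MixtureFitResult,
    MixtureParams,
    SymmetricZMixture,
    bootstrap_inference,
    expected_affected,
    fit_mixture,
    mixture_loglik,
    sample_mixture,
)

TRUE = MixtureParams(pi_minus=0.0, pi_zero=0.769, pi_plus=0.231, mu_z=1.003)


class TestParams:
    def test_simplex_validation(self):
        with pytest.raises(ValueError):
            MixtureParams(0.5, 0.6, -0.1, 1.0)
        with pytest.raises(ValueError):
            MixtureParams(0.5, 0.4, 0.2, 1.0)
        with pytest.raises(ValueError):
            MixtureParams(0.0, 1.0, 0.0, -0.5)


class TestLoglik:
    def test_single_standard_normal_point(self):
        params = MixtureParams(0.0, 1.0, 0.0, 1.0)
        assert mixture_loglik(params, [0.0]) == pytest.approx(-0.9189385332046727, abs=1e-12)

    def test_reflection_symmetry(self, rng):
        z = rng.normal(0.3, 1.2, 50)
        p = MixtureParams(0.2, 0.5, 0.3, 1.4)
        p_swap = MixtureParams(0.3, 0.5, 0.2, 1.4)
        assert mixture_loglik(p, z) == pytest.approx(mixture_loglik(p_swap, -z), rel=1e-12)

    def test_direct_summation_oracle(self):
        """Frozen value computed by 30-digit direct summation of the density."""
        p = MixtureParams(0.2, 0.5, 0.3, 1.0)
        assert mixture_loglik(p, [0.5, -1.2, 2.1]) == pytest.approx(
            -5.291818038513565, abs=1e-12
        )

    def test_rejects_bad_input(self):
        p = MixtureParams(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            mixture_loglik(p, [])
        with pytest.raises(ValueError):
            mixture_loglik(p, [np.nan])


class TestFit:
    def test_null_data_fits_effectively_null_model(self):
        """On pure-noise Z scores the fitted mixture is the standard normal in
        distribution: the null weight dominates and any non-null mass sits at
        a vanishing shift (the weights alone are not identifiable there)."""
        z = np.random.default_rng(5).normal(0.0, 1.0, 2000)
        fit = fit_mixture(z, seed=2)
        p = fit.params
        assert p.pi_zero > 0.8
        assert abs((p.pi_plus - p.pi_minus) * p.mu_z) < 0.05
        # fitted density indistinguishable from N(0,1): max CDF gap tiny
        grid = np.linspace(-4, 4, 201)
        fitted_cdf = (
            p.pi_minus * norm.cdf(grid + p.mu_z)
            + p.pi_zero * norm.cdf(grid)
            + p.pi_plus * norm.cdf(grid - p.mu_z)
        )
        assert np.max(np.abs(fitted_cdf - norm.cdf(grid))) < 0.02

    def test_single_shifted_component_recovery(self):
        z = np.random.default_rng(5).normal(3.0, 1.0, 2000)
        fit = fit_mixture(z, seed=2)
        assert fit.params.pi_plus >= 0.95
        assert abs(fit.params.mu_z - 3.0) <= 0.1

    def test_label_symmetry(self, rng):
        z = sample_mixture(TRUE, 131, rng)
        f1 = fit_mixture(z, seed=9)
        f2 = fit_mixture(-z, seed=9)
        assert f1.params.pi_plus == pytest.approx(f2.params.pi_minus, abs=1e-3)
        assert f1.params.pi_minus == pytest.approx(f2.params.pi_plus, abs=1e-3)
        assert f1.params.mu_z == pytest.approx(f2.params.mu_z, abs=1e-3)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)

    def test_loglik_never_below_null_model(self, rng):
        for _ in range(5):
            z = rng.normal(rng.uniform(-1, 1), 1.0, 100)
            fit = fit_mixture(z, seed=1)
            null_ll = float(norm.logpdf(z).sum())
            assert fit.loglik >= null_ll - 1e-9

    def test_weights_on_simplex(self, rng):
        z = sample_mixture(TRUE, 200, rng)
        fit = fit_mixture(z, seed=4)
        w = fit.params.weights
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12
        assert fit.params.mu_z >= 0

    def test_deterministic_given_seed(self, rng):
        z = sample_mixture(TRUE, 131, rng)
        f1 = fit_mixture(z, seed=77)
        f2 = fit_mixture(z, seed=77)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_requires_enough_points(self):
        with pytest.raises(ValueError):
            fit_mixture([0.1, 0.2, 0.3])

    def test_sklearn_protocol(self, rng):
        est = SymmetricZMixture(n_restarts=5, random_state=0)
        z = sample_mixture(TRUE, 131, rng)
        est.fit(z)
        proba = est.predict_proba(z)
        assert proba.shape == (131, 3)
        assert np.allclose(proba.sum(axis=1), 1.0)
        labels = est.predict(z)
        assert set(np.unique(labels)) <= {-1, 0, 1}
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est2.set_params(n_restarts=3)
        assert est2.n_restarts == 3


class TestExpectedAffected:
    def test_panel_scale_arithmetic(self):
        expected, rounded = expected_affected(MixtureParams(0.0, 0.769, 0.231, 1.003), 131)
        assert expected == pytest.approx(30.261, abs=1e-9)
        assert rounded == 30

    def test_degenerate_weights(self):
        assert expected_affected(MixtureParams(0.0, 1.0, 0.0, 1.0), 131) == (0.0, 0)
        assert expected_affected(MixtureParams(0.0, 0.0, 1.0, 1.0), 10) == (10.0, 10)


@pytest.fixture(scope="module")
def panel_fit():
    z = sample_mixture(TRUE, 131, np.random.default_rng(17))
    return z, fit_mixture(z, seed=17)


class TestBootstrap:

    def test_deterministic_given_seed(self, panel_fit):
        z, fit = panel_fit
        r1 = bootstrap_inference(z, fit, n_boot=100, seed=5)
        r2 = bootstrap_inference(z, fit, n_boot=100, seed=5)
        assert r1.boot_se == r2.boot_se
        assert r1.boot_p == r2.boot_p

    def test_zero_estimate_reports_p_one(self, panel_fit):
        z, fit = panel_fit
        forced = dataclasses.replace(
            fit, params=MixtureParams(0.0, 1.0 - fit.params.pi_plus, fit.params.pi_plus, fit.params.mu_z)
        )
        res = bootstrap_inference(z, forced, n_boot=100, seed=5)
        assert res.boot_p["pi_minus"] == 1.0
        assert 0.0 <= min(res.boot_p.values()) and max(res.boot_p.values()) <= 1.0

    def test_rejects_tiny_n_boot(self, panel_fit):
        z, fit = panel_fit
        with pytest.raises(ValueError):
            bootstrap_inference(z, fit, n_boot=50, seed=1)
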