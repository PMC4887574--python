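"""Multivariate REML meta-regression against univariate and GLS oracles."""

import numpy as np
import pytest
from scipy import optimize, stats

import heatlag as hl
from heatlag.mvmeta import _gls, blup, build_meta_design, fit_mvmeta_reml, predict_country, wald_test_interaction


def univariate_reml_oracle(y, s2):
    """Independently coded univariate random-effects REML (profile likelihood)."""
    y = np.asarray(y, dtype=float)
    s2 = np.asarray(s2, dtype=float)

    def neg_ll(tau2):
        w = 1.0 / (s2 + tau2)
        mu = np.sum(w * y) / np.sum(w)
        ll = -0.5 * (
            np.sum(np.log(s2 + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
            + (len(y) - 1) * np.log(2 * np.pi)
        )
        return -ll

    res = optimize.minimize_scalar(neg_ll, bounds=(0.0, 100.0), method="bounded",
                                   options={"xatol": 1e-14})
    tau2 = res.x
    w = 1.0 / (s2 + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return mu, tau2, -res.fun


@pytest.fixture(scope="module")
def univariate_studies():
    rng = np.random.default_rng(314)
    n = 20
    s2 = rng.uniform(0.02, 0.2, n)
    tau2_true = 0.05
    y = 0.3 + rng.normal(0, np.sqrt(tau2_true + s2))
    return y, s2


class TestUnivariateEquivalence:
    def test_matches_univariate_reml_oracle(self, univariate_studies):
        y, s2 = univariate_studies
        mu_o, tau2_o, ll_o = univariate_reml_oracle(y, s2)
        fit = fit_mvmeta_reml(y[:, None], s2[:, None, None], np.ones((len(y), 1)),
                              gtol=1e-12)
        assert fit.beta[0, 0] == pytest.approx(mu_o, abs=1e-8)
        assert fit.psi[0, 0] == pytest.approx(tau2_o, abs=1e-8)
        assert fit.loglik == pytest.approx(ll_o, abs=1e-8)


class TestGLSClosedForm:
    def test_psi_zero_is_inverse_variance_weighting(self):
        rng = np.random.default_rng(1)
        n = 12
        y = rng.normal(size=(n, 1))
        s2 = rng.uniform(0.1, 0.5, n)
        W = (1.0 / s2)[:, None, None]
        b, A_inv, _ = _gls(y, np.ones((n, 1)), W)
        want = np.sum(y[:, 0] / s2) / np.sum(1 / s2)
        assert b[0] == pytest.approx(want, rel=1e-12)
        assert A_inv[0, 0] == pytest.approx(1 / np.sum(1 / s2), rel=1e-12)

    def test_one_location_returns_its_estimate(self):
        y = np.array([[0.7]])
        fit = fit_mvmeta_reml(y, np.array([[[0.2]]]), np.ones((1, 1)))
        assert fit.beta[0, 0] == pytest.approx(0.7, abs=1e-8)


class TestParameterRecovery:
    def test_recovers_fixed_effects_and_psi(self):
        """200 locations, k=3: B within normal error, Psi within 20% Frobenius."""
        rng = np.random.default_rng(2024)
        n, k = 200, 3
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        B = np.array([[0.3, -0.1, 0.2], [0.05, 0.02, -0.03]])
        L = np.array([[0.2, 0, 0], [0.05, 0.15, 0], [0.0, 0.02, 0.1]])
        psi = L @ L.T
        S = np.array([np.diag(rng.uniform(0.005, 0.05, k)) for _ in range(n)])
        y = X @ B + rng.multivariate_normal(np.zeros(k), psi, n)
        y += np.array([rng.multivariate_normal(np.zeros(k), S[i]) for i in range(n)])
        fit = fit_mvmeta_reml(y, S, X)
        se = np.sqrt(np.diag(fit.vcov)).reshape(2, k)
        assert np.all(np.abs(fit.beta - B) < 4 * se)
        assert np.linalg.norm(fit.psi - psi) < 0.2 * np.linalg.norm(psi)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        n, k = 15, 2
        y = rng.normal(size=(n, k))
        S = np.array([np.eye(k) * rng.uniform(0.1, 0.3) for _ in range(n)])
        X = np.ones((n, 1))
        f1 = fit_mvmeta_reml(y, S, X)
        f2 = fit_mvmeta_reml(y + np.array([5.0, -3.0]), S, X)
        assert np.abs(f1.psi - f2.psi).max() < 1e-6
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


@pytest.fixture(scope="module")
def meta_fit():
    rng = np.random.default_rng(55)
    n, k = 24, 3
    countries = ["A"] * 12 + ["B"] * 12
    tm = rng.normal(22, 1.5, n)
    tr = rng.uniform(12, 18, n)
    X, cols, means = build_meta_design(countries, tm, tr)
    B = rng.normal(0, 0.2, size=(X.shape[1], k))
    y = X @ B + rng.normal(0, 0.1, size=(n, k))
    S = np.array([np.eye(k) * 0.02 for _ in range(n)])
    return fit_mvmeta_reml(y, S, X, columns=cols, covariate_means=means)


class TestPredictAndBlup:
    def test_prediction_variance_is_contrast_form(self, meta_fit):
        b, v = predict_country(meta_fit, "A", {})
        x = np.zeros(meta_fit.inputs.X.shape[1])
        x[0] = 1.0
        U = np.kron(x[None, :], np.eye(3))
        assert np.abs(v - U @ meta_fit.vcov @ U.T).max() < 1e-12

    def test_unknown_country_rejected(self, meta_fit):
        with pytest.raises(ValueError, match="country"):
            predict_country(meta_fit, "Z", {})

    def test_extrapolation_warns(self, meta_fit):
        with pytest.warns(UserWarning, match="outside"):
            predict_country(meta_fit, "A", {"temp_mean": 99.0})

    def test_blup_reduces_to_fixed_when_psi_zero(self, meta_fit):
        import dataclasses

        fit0 = dataclasses.replace(meta_fit, psi=np.zeros((3, 3)))
        preds, _ = blup(fit0)
        fitted = fit0.inputs.X @ fit0.beta
        assert np.abs(preds - fitted).max() < 1e-12

    def test_blup_approaches_data_when_s_tiny(self):
        rng = np.random.default_rng(4)
        n, k = 10, 1
        y = rng.normal(size=(n, k))
        S = np.full((n, k, k), 1e-12)
        fit = fit_mvmeta_reml(y, S, np.ones((n, 1)))
        preds, _ = blup(fit)
        assert np.abs(preds - y).max() < 1e-4

    def test_scalar_blup_shrinks_between_data_and_pooled(self):
        rng = np.random.default_rng(12)
        n = 30
        y = rng.normal(0.5, 0.4, size=(n, 1))
        S = np.array([[[s]] for s in rng.uniform(0.05, 0.3, n)])
        fit = fit_mvmeta_reml(y, S, np.ones((n, 1)))
        preds, _ = blup(fit)
        pooled = fit.beta[0, 0]
        lo = np.minimum(y[:, 0], pooled) - 1e-12
        hi = np.maximum(y[:, 0], pooled) + 1e-12
        assert np.all((preds[:, 0] >= lo) & (preds[:, 0] <= hi))


class TestWald:
    def test_zero_vector_gives_p_one(self):
        stat, df, p = wald_test_interaction(np.zeros(3), np.eye(3))
        assert stat == 0.0 and df == 3 and p == 1.0

    def test_scalar_matches_z_test(self):
        b, se = 0.3, 0.12
        stat, df, p = wald_test_interaction(np.array([b]), np.array([[se**2]]))
        assert stat == pytest.approx((b / se) ** 2)
        assert p == pytest.approx(2 * stats.norm.sf(abs(b / se)), rel=1e-12)

    def test_interaction_symmetry_with_late_minus_early(self, small_series):
        """Pooling the interaction equals the scaled late-early difference."""
        f = hl.fit_location(small_series)
        d_e, d_l = 15, 107
        diff = f.late_overall.coefficients - f.early_overall.coefficients
        scaled = (d_l - d_e) * f.interaction_overall.coefficients
        assert np.abs(diff - scaled).max() < 1e-8
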