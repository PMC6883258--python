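import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hdma import (
    debias_linear,
    debias_logistic,
    fit_lasso,
    nodewise_lasso,
    pvalues_from_fit,
    scaled_lasso_sigma,
)
from hdma.inference import _expit


def _orthonormal_design(rng, n=128, p=6):
    """Columns with mean 0, sd 1 and Gram X'X/n = I (soft-threshold oracle)."""
    raw = rng.standard_normal((n, p))
    raw -= raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    return Q * math.sqrt(n)


def _soft(b, lam):
    return np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)


class TestFitLasso:
    def test_unpenalized_limit_equals_ols(self, rng):
        X = _orthonormal_design(rng)
        y = X @ np.array([1.0, -0.5, 0.3, 0, 0, 0.2]) + rng.standard_normal(128)
        fit = fit_lasso(X, y, lambda_=0.0)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(128), X]), y, rcond=None
        )[0]
        assert np.allclose(fit.coefficients, ols[1:], atol=1e-8)

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        X = _orthonormal_design(rng)
        y = X @ np.array([1.0, -0.5, 0.3, 0, 0, 0.2]) + rng.standard_normal(128)
        lam = 0.25
        fit = fit_lasso(X, y, lambda_=lam)
        ols = X.T @ (y - y.mean()) / 128
        assert np.allclose(fit.coefficients, _soft(ols, lam), atol=1e-8)

    def test_large_lambda_kills_penalized_coefficients(self, rng):
        X = rng.standard_normal((80, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(80)
        fit = fit_lasso(X, y, lambda_=1e3)
        assert np.all(fit.coefficients == 0)

    def test_unpenalized_columns_survive_large_lambda(self, rng):
        X = rng.standard_normal((200, 5))
        y = 2.0 * X[:, 0] + rng.standard_normal(200)
        mask = np.array([True, False, False, False, False])
        fit = fit_lasso(X, y, lambda_=1e3, unpenalized_mask=mask)
        assert abs(fit.coefficients[0] - 2.0) < 0.3
        assert np.all(fit.coefficients[1:] == 0)

    def test_logistic_lambda_zero_matches_mle(self, rng):
        n = 1500
        X = rng.standard_normal((n, 3))
        eta = -0.5 + X @ np.array([0.8, -0.4, 0.0])
        y = (rng.random(n) < _expit(eta)).astype(float)
        fit = fit_lasso(X, y, lambda_=1e-8, family="binary")
        mle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coefficients, mle.params[1:], atol=1e-4)
        assert fit.intercept == pytest.approx(mle.params[0], abs=1e-4)

    def test_constant_response_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            fit_lasso(X, np.ones(30))


class TestNodewise:
    def test_orthogonal_columns_give_trivial_residual(self, rng):
        A = _orthonormal_design(rng, n=100, p=4)
        nd = nodewise_lasso(A, 1, 0.2)
        assert np.allclose(nd.gamma, 0.0)
        assert np.allclose(nd.residual, A[:, 1])

    def test_collinear_columns_raise_degeneracy(self, rng):
        a = rng.standard_normal(60)
        A = np.column_stack([a, a])
        with pytest.raises(np.linalg.LinAlgError):
            nodewise_lasso(A, 0, 0.0)

    def test_near_orthogonalization_on_ar_design(self, rng):
        # strongly correlated design: residual Z_j should be nearly
        # orthogonal to every other column relative to Z_j'M_j
        n, p, rho = 500, 20, 0.8
        z = rng.standard_normal((n, p))
        A = np.empty((n, p))
        A[:, 0] = z[:, 0]
        for j in range(1, p):
            A[:, j] = rho * A[:, j - 1] + math.sqrt(1 - rho**2) * z[:, j]
        nd = nodewise_lasso(A, 10, 0.01)
        zm = nd.residual @ A[:, 10]
        ratios = [abs(nd.residual @ A[:, l] / zm) for l in range(p) if l != 10]
        assert max(ratios) < 0.05


class TestScaledLasso:
    def test_recovers_unit_noise_scale(self, rng):
        n, p = 2000, 50
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        sigma, coef = scaled_lasso_sigma(X, y)
        assert sigma == pytest.approx(1.0, rel=0.10)

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((400, 20))
        y = X[:, 0] + rng.standard_normal(400)
        s1, _ = scaled_lasso_sigma(X, y)
        s2, _ = scaled_lasso_sigma(X, 2.0 * y)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-6)

    def test_noiseless_response_drives_sigma_to_zero(self, rng):
        X = rng.standard_normal((300, 5))
        y = X @ np.array([1.0, 2.0, 0.0, 0.0, -1.0])
        sigma, _ = scaled_lasso_sigma(X, y)
        assert sigma < 0.05


class TestDebiasLinear:
    def test_equals_ols_in_unpenalized_regime(self, rng):
        """p << n with lambda=0 everywhere: exact OLS coefficients and se."""
        n, p = 200, 30
        X = rng.standard_normal((n, p))
        y = X @ np.concatenate([np.ones(3), np.zeros(p - 3)]) + rng.standard_normal(n)
        fit = debias_linear(X, y, lambda_=0.0, nodewise_lambdas=0.0)
        D = np.column_stack([np.ones(n), X])
        ols = sm.OLS(y, D).fit()
        assert np.allclose(fit.estimates, ols.params[1:], atol=1e-8)
        # OLS standard errors with the scaled-lasso sigma plugged in
        xtx_inv = np.linalg.inv(D.T @ D)
        expected_se = fit.sigma_eps * np.sqrt(np.diag(xtx_inv)[1:])
        assert np.allclose(fit.se, expected_se, atol=1e-8)

    def test_single_column_design_is_plain_slope(self, rng):
        n = 150
        X = np.column_stack([rng.standard_normal(n), rng.standard_normal(n)])
        y = 1.5 * X[:, 0] + rng.standard_normal(n)
        fit = debias_linear(X, y, lambda_=0.01, nodewise_lambdas=0.3)
        assert fit.estimates[0] == pytest.approx(1.5, abs=0.3)

    def test_debiasing_reduces_shrinkage_bias(self, rng):
        """Mean debiased estimate is closer to truth than the LASSO mean."""
        truth = 1.0
        lam = 0.3
        err_lasso, err_deb = [], []
        for _ in range(120):
            X = _orthonormal_design(rng, n=100, p=5)
            y = truth * X[:, 0] + rng.standard_normal(100)
            fit = debias_linear(X, y, lambda_=lam, nodewise_lambdas=0.05)
            err_lasso.append(fit.lasso.coefficients[0])
            err_deb.append(fit.estimates[0])
        assert abs(np.mean(err_deb) - truth) < abs(np.mean(err_lasso) - truth)
        assert abs(np.mean(err_deb) - truth) < 0.05

    def test_null_pvalues_are_uniform(self, rng):
        pvals = []
        for _ in range(150):
            X = rng.standard_normal((120, 20))
            y = rng.standard_normal(120)
            fit = debias_linear(X, y)
            pvals.extend(fit.pvalues[:4])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDebiasLogistic:
    def test_matches_mle_in_low_dimension(self, rng):
        n = 2000
        X = rng.standard_normal((n, 3))
        beta = np.array([0.6, -0.3, 0.0])
        y = (rng.random(n) < _expit(-0.4 + X @ beta)).astype(float)
        fit = debias_logistic(X, y, lambda_=1e-6, nodewise_lambdas=1e-8,
                              df_correction=False)
        mle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.all(np.abs(fit.estimates - mle.params[1:]) < 2 * mle.bse[1:])
        wald_p = mle.pvalues[1:]
        assert np.all(np.abs(fit.pvalues - wald_p) < 0.02)

    def test_label_flip_negates_estimates_keeps_pvalues(self, rng):
        n = 400
        X = rng.standard_normal((n, 8))
        y = (rng.random(n) < _expit(X[:, 0])).astype(float)
        f1 = debias_logistic(X, y, lambda_=0.05)
        f2 = debias_logistic(X, 1.0 - y, lambda_=0.05)
        assert np.allclose(f1.estimates, -f2.estimates, atol=1e-6)
        assert np.allclose(f1.pvalues, f2.pvalues, atol=1e-6)

    def test_global_null_type_one_error_controlled(self, rng):
        rej, tot = 0, 0
        for _ in range(60):
            n, p = 300, 50
            X = rng.standard_normal((n, p))
            y = (rng.random(n) < 0.35).astype(float)
            fit = debias_logistic(X, y)
            rej += (fit.pvalues < 0.05).sum()
            tot += p
        assert 0.02 <= rej / tot <= 0.07

    def test_non_binary_response_rejected(self, rng):
        X = rng.standard_normal((50, 4))
        with pytest.raises(ValueError):
            debias_logistic(X, rng.standard_normal(50))


class TestPvalues:
    def test_identities(self):
        X = np.random.default_rng(0).standard_normal((60, 3))
        y = X[:, 0] + np.random.default_rng(1).standard_normal(60)
        fit = debias_linear(X, y, lambda_=0.05)
        object.__setattr__(fit, "z", np.array([0.0, 1.959964, -1.959964]))
        pv = pvalues_from_fit(fit)
        assert pv[0] == pytest.approx(1.0)
        assert pv[1] == pytest.approx(0.05, abs=1e-6)
        assert pv[2] == pv[1]

    @given(z1=st.floats(0, 10), z2=st.floats(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_in_abs_z(self, z1, z2):
        p1 = 2 * stats.norm.sf(abs(z1))
        p2 = 2 * stats.norm.sf(abs(z2))
        if abs(z1) <= abs(z2):
            assert p1 >= p2
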