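import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdma import (
    SimulationConfig,
    ar1_covariance,
    default_a_vec,
    default_b_vec,
    generate_exposure,
    generate_mediators,
    generate_outcome,
    simulate_dataset,
    total_effect_true,
)


class TestAr1Covariance:
    def test_rho_zero_is_identity(self):
        assert np.array_equal(ar1_covariance(3, 0.0), np.eye(3))

    def test_entries_follow_geometric_decay(self):
        S = ar1_covariance(3, 0.8)
        assert S[0, 1] == pytest.approx(0.8)
        assert S[0, 2] == pytest.approx(0.64)
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            ar1_covariance(5, rho)

    @given(k=st.integers(2, 40), rho=st.floats(0.0, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_positive_definite(self, k, rho):
        np.linalg.cholesky(ar1_covariance(k, rho))  # raises if not PD


class TestExposure:
    def test_mean_matches_bernoulli_probability(self, rng):
        x = generate_exposure(10_000, 0.74, rng)
        assert set(np.unique(x)) <= {0.0, 1.0}
        assert abs(x.mean() - 0.74) < 3 * np.sqrt(0.74 * 0.26 / 10_000)

    def test_variance_matches_bernoulli(self, rng):
        x = generate_exposure(100_000, 0.74, rng)
        assert x.var() == pytest.approx(0.74 * 0.26, abs=0.004)

    def test_seed_determinism(self):
        a = generate_exposure(50, 0.5, np.random.default_rng(3))
        b = generate_exposure(50, 0.5, np.random.default_rng(3))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2])
    def test_degenerate_probability_rejected(self, p, rng):
        with pytest.raises(ValueError):
            generate_exposure(10, p, rng)


class TestMediators:
    def test_recursion_equals_cholesky_transform(self):
        """The O(nk) AR(1) recursion is exactly the Cholesky-factor sampler."""
        cfg = SimulationConfig(n=50, k=12, rho=0.7, seed=0)
        X = np.zeros(50)
        M = generate_mediators(X, cfg, np.random.default_rng(99))
        z = np.random.default_rng(99).standard_normal((50, 12))
        L = np.linalg.cholesky(ar1_covariance(12, 0.7))
        expected = cfg.theta_prime + z @ L.T
        assert np.allclose(M, expected, atol=1e-12)

    def test_column_means_hit_intercept_when_x_zero(self):
        cfg = SimulationConfig(n=10_000, k=10, rho=0.0, seed=1)
        M = generate_mediators(np.zeros(10_000), cfg, np.random.default_rng(1))
        assert np.allclose(M.mean(axis=0), 1.0, atol=0.05)
        corr = np.corrcoef(M.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_adjacent_correlation_tracks_rho(self):
        cfg = SimulationConfig(n=10_000, k=10, rho=0.8, seed=2)
        M = generate_mediators(np.zeros(10_000), cfg, np.random.default_rng(2))
        corr = np.corrcoef(M.T)
        adj = np.diag(corr, k=1)
        assert np.allclose(adj, 0.8, atol=0.03)
        assert np.allclose(np.diag(corr, k=2), 0.64, atol=0.03)

    def test_exposure_shifts_means_by_a(self):
        cfg = SimulationConfig(n=20_000, k=8, rho=0.0, seed=3)
        M = generate_mediators(np.ones(20_000), cfg, np.random.default_rng(3))
        assert np.allclose(M.mean(axis=0), 1.0 + cfg.a_vec, atol=0.05)

    def test_shape_mismatch_rejected(self, rng):
        cfg = SimulationConfig(n=30, k=8)
        with pytest.raises(ValueError):
            generate_mediators(np.zeros(10), cfg, rng)


class TestOutcome:
    def test_null_prevalence_matches_logistic_intercept(self):
        cfg = SimulationConfig(
            n=100_000, k=8, a_vec=np.zeros(8), b_vec=np.zeros(8), seed=4
        )
        rng = np.random.default_rng(4)
        X = generate_exposure(cfg.n, cfg.exposure_prob, rng)
        M = generate_mediators(X, cfg, rng)
        Y = generate_outcome(X, M, cfg, rng)
        expected = 1.0 / (1.0 + np.exp(4.5))
        assert Y.mean() == pytest.approx(expected, abs=3 * np.sqrt(expected / cfg.n))

    def test_default_design_raises_prevalence(self):
        data = simulate_dataset(SimulationConfig(n=50_000, k=20, seed=5))
        assert data.Y.mean() > 1.0 / (1.0 + np.exp(4.5))

    def test_continuous_family_is_gaussian_around_linear_predictor(self):
        cfg = SimulationConfig(n=50_000, k=8, family="continuous", seed=6)
        rng = np.random.default_rng(6)
        X = generate_exposure(cfg.n, cfg.exposure_prob, rng)
        M = generate_mediators(X, cfg, rng)
        Y = generate_outcome(X, M, cfg, rng)
        eta = cfg.theta2 + cfg.c_prime * X + M @ cfg.b_vec
        resid = Y - eta
        assert abs(resid.mean()) < 0.02
        assert resid.std() == pytest.approx(1.0, abs=0.02)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n=20, k=8, family="poisson")


class TestTotalEffect:
    def test_complete_mediation_design(self):
        a, b = default_a_vec(100), default_b_vec(100)
        assert total_effect_true(a, b, 0.0) == pytest.approx(0.94, abs=1e-12)

    def test_partial_mediation_design(self):
        a, b = default_a_vec(1000), default_b_vec(1000)
        assert total_effect_true(a, b, 0.5) == pytest.approx(1.44, abs=1e-12)

    def test_no_indirect_effect_reduces_to_direct(self):
        assert total_effect_true(np.zeros(8), default_b_vec(8), 0.5) == 0.5

    @given(c=st.floats(-2, 2), scale=st.floats(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_each_argument(self, c, scale):
        a, b = default_a_vec(10), default_b_vec(10)
        base = total_effect_true(a, b, 0.0)
        assert total_effect_true(a * scale, b, c) == pytest.approx(
            scale * base + c, rel=1e-12, abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_effect_true(np.zeros(3), np.zeros(4), 0.0)


class TestDatasetInvariants:
    def test_truth_has_exactly_four_true_mediators(self):
        data = simulate_dataset(SimulationConfig(n=50, k=200, seed=8))
        assert data.truth.sum() == 4
        assert np.array_equal(np.flatnonzero(data.truth), [0, 1, 2, 3])

    def test_null_kinds_distinguishable_from_config(self):
        cfg = SimulationConfig(n=50, k=10, seed=8)
        a_only = (cfg.a_vec != 0) & (cfg.b_vec == 0)
        b_only = (cfg.a_vec == 0) & (cfg.b_vec != 0)
        assert np.array_equal(np.flatnonzero(a_only), [4, 5])
        assert np.array_equal(np.flatnonzero(b_only), [6, 7])

    def test_full_pipeline_determinism(self):
        cfg = SimulationConfig(n=80, k=16, rho=0.5, seed=21)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(d1.X, d2.X)
        assert np.array_equal(d1.M, d2.M)
        assert np.array_equal(d1.Y, d2.Y)

    def test_binary_outputs_are_binary(self, small_binary_dataset):
        assert set(np.unique(small_binary_dataset.X)) <= {0.0, 1.0}
        assert set(np.unique(small_binary_dataset.Y)) <= {0.0, 1.0}

    @pytest.mark.parametrize("kwargs", [dict(n=1), dict(k=7), dict(rho=1.0)])
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n=20, k=8)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimulationConfig(**base)
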