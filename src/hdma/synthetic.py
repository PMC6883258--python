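"""Synthetic exposure/mediator/outcome data for high-dimensional mediation.

Generates datasets with the structure used throughout the package's
simulation study: a binary exposure X ~ Bernoulli(p), mediators drawn from a
multivariate normal with mean theta' + a_j * X and AR(1) correlation
Sigma_st = rho^|s-t|, and an outcome that is either logistic-Bernoulli
(binary family) or linear-Gaussian (continuous family) in X and the
mediators.  Under the default coefficient vectors exactly mediators 1-4
carry a nonzero indirect effect a_j * b_j; mediators 5-6 are nulls with
a != 0, b = 0 and mediators 7-8 are nulls with a = 0, b != 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_a_vec",
    "default_b_vec",
    "ar1_covariance",
    "generate_exposure",
    "generate_mediators",
    "generate_outcome",
    "total_effect_true",
    "simulate_dataset",
]

# Leading coefficients of the default design; the remaining k-8 entries are 0.
_B_HEAD = (0.8, 0.7, 0.6, 0.5, 0.0, 0.0, 0.5, 0.5)
_A_HEAD = (0.35, 0.25, 0.35, 0.55, 0.55, 0.55, 0.0, 0.0)


def default_a_vec(k: int) -> np.ndarray:
    """Default exposure->mediator coefficients (length k, first 8 nonzero pattern)."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    a = np.zeros(k)
    a[:8] = _A_HEAD
    return a


def default_b_vec(k: int) -> np.ndarray:
    """Default mediator->outcome coefficients (length k, first 8 nonzero pattern)."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    b = np.zeros(k)
    b[:8] = _B_HEAD
    return b


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of one simulation scenario.

    Parameters
    ----------
    n : sample size (>= 2).
    k : number of mediators (>= 8).
    rho : AR(1) correlation between mediators, 0 <= rho < 1.
    a_vec, b_vec : length-k path coefficients; ``None`` uses the default
        sparse vectors (first 8 entries as in the study design, rest zero).
    c_prime : direct exposure->outcome effect (0 gives complete mediation).
    theta2 : outcome-model intercept (logistic scale for the binary family).
    theta_prime : mediator-model intercept.
    exposure_prob : Bernoulli success probability of the exposure.
    family : "binary" (logistic outcome) or "continuous" (Gaussian noise,
        unit variance).
    seed : RNG seed; the full dataset is a deterministic function of the
        config including this seed.
    """

    n: int
    k: int = 100
    rho: float = 0.0
    a_vec: np.ndarray | None = None
    b_vec: np.ndarray | None = None
    c_prime: float = 0.0
    theta2: float = -4.5
    theta_prime: float = 1.0
    exposure_prob: float = 0.74
    family: str = "binary"
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.k < 8:
            raise ValueError(f"k must be >= 8, got {self.k}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not (0.0 < self.exposure_prob < 1.0):
            raise ValueError("exposure_prob must be in (0, 1)")
        if self.family not in ("binary", "continuous"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "a_vec", self._coerce(self.a_vec, default_a_vec))
        object.__setattr__(self, "b_vec", self._coerce(self.b_vec, default_b_vec))

    def _coerce(self, vec, default):
        if vec is None:
            return default(self.k)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.k,):
            raise ValueError(f"coefficient vector must have shape ({self.k},)")
        return vec

    @property
    def truth(self) -> np.ndarray:
        """Indicator of true mediators: nonzero indirect effect a_j * b_j."""
        return (self.a_vec * self.b_vec != 0).astype(int)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SimulatedDataset:
    """One realisation of a simulation scenario."""

    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    truth: np.ndarray
    config: SimulationConfig

    def __post_init__(self):
        n, k = self.config.n, self.config.k
        if self.X.shape != (n,) or self.Y.shape != (n,) or self.M.shape != (n, k):
            raise ValueError("dataset arrays inconsistent with config dimensions")


def ar1_covariance(k: int, rho: float) -> np.ndarray:
    """AR(1) covariance matrix with entries rho^|s-t| (unit diagonal)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_exposure(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Bernoulli(p) exposure indicators."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    return (rng.random(n) < p).astype(float)


def generate_mediators(
    X: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the n x k mediator matrix: row i ~ MVN(theta' + a * X_i, Sigma).

    Sampling uses the exact AR(1) recursion e_1 = z_1,
    e_j = rho * e_{j-1} + sqrt(1 - rho^2) * z_j with z ~ N(0, I), which
    reproduces the Cholesky factor of the AR(1) covariance in O(nk) and
    stays feasible for k in the thousands.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 1 or X.shape[0] != config.n:
        raise ValueError("X must be a length-n vector matching config.n")
    n, k, rho = config.n, config.k, config.rho
    z = rng.standard_normal((n, k))
    eps = np.empty((n, k))
    eps[:, 0] = z[:, 0]
    if k > 1:
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, k):
            eps[:, j] = rho * eps[:, j - 1] + scale * z[:, j]
    mean = config.theta_prime + np.outer(X, config.a_vec)
    return mean + eps


def generate_outcome(
    X: np.ndarray, M: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the outcome given exposure and mediators.

    Binary family: Y_i ~ Bernoulli(expit(eta_i)) with
    eta_i = theta2 + c' X_i + sum_j b_j M_ij.  Continuous family:
    Y_i = eta_i + N(0, 1).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.shape != (X.shape[0], config.k):
        raise ValueError("X and M have inconsistent shapes")
    eta = config.theta2 + config.c_prime * X + M @ config.b_vec
    if config.family == "binary":
        p = 1.0 / (1.0 + np.exp(-eta))
        return (rng.random(eta.shape[0]) < p).astype(float)
    if config.family == "continuous":
        return eta + rng.standard_normal(eta.shape[0])
    raise ValueError(f"unknown family {config.family!r}")


def total_effect_true(a_vec, b_vec, c_prime: float) -> float:
    """Population total effect c = c' + sum_j a_j b_j."""
    a = np.asarray(a_vec, dtype=float)
    b = np.asarray(b_vec, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a_vec and b_vec must have equal length")
    return float(c_prime + a @ b)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one (X, M, Y) realisation plus ground-truth mediation flags."""
    rng = np.random.default_rng(config.seed)
    X = generate_exposure(config.n, config.exposure_prob, rng)
    M = generate_mediators(X, config, rng)
    Y = generate_outcome(X, M, config, rng)
    return SimulatedDataset(X=X, M=M, Y=Y, truth=config.truth, config=config)
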