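"""Joint-significance testing of high-dimensional mediation effects.

The full pipeline for one dataset:

1. SIS screening keeps the top d = ceil(n / (divisor * ln n)) mediators.
2. De-sparsified LASSO inference on the outcome model
   E(Y) = theta2 + c' X + sum_j b_j M_j (+ covariates) gives per-mediator
   debiased estimates b_hat and p-values p_b.
3. The candidate set S = {t : p_b,t < alpha}; for each retained mediator the
   exposure->mediator path is fit by OLS, M_t ~ X (+ covariates), giving
   a_hat and p_a = 2(1 - Phi(|a_hat|/se)).
4. The joint-significance (intersection-union) p-value is
   P*_t = max(p_a, p_b); mediator t is declared significant when both
   component tests reject at alpha.

Effect decomposition reports the indirect effect a_hat * b_hat and its share
of the total effect |a_hat b_hat| / |c_hat| * 100, with c_hat from the
marginal model of Y on X (+ covariates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import inference, screening

logger = logging.getLogger(__name__)

__all__ = [
    "TestConfig",
    "MediationResult",
    "fit_total_effect",
    "fit_alpha_path",
    "joint_pvalue",
    "effect_decomposition",
    "hdma_test",
]

#: schema of the per-mediator results table
RESULT_COLUMNS = [
    "mediator_id",
    "tested",
    "a_hat",
    "se_a",
    "p_a",
    "b_hat",
    "se_b",
    "p_b",
    "ab",
    "pct_total_effect",
    "p_joint",
    "significant",
]


@dataclass(frozen=True)
class TestConfig:
    """Knobs of the mediation testing pipeline."""

    alpha: float = 0.05
    sis_divisor: float = 1.0
    sis_basis: str = "outcome_model"
    #: None -> family default ("plugin" rate for binary, 10-fold CV for
    #: continuous); or "cv" | "plugin" | an explicit number
    lambda_: object = None
    nodewise_lambdas: object = "plugin"  # "plugin" | "cv" | scalar/vector
    correction: str | None = None  # None | "bonferroni" | "fdr_bh"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in (None, "bonferroni", "fdr_bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class MediationResult:
    """Per-mediator mediation tests plus global effect estimates.

    ``table`` has one row per input mediator (RESULT_COLUMNS schema);
    mediators screened out have ``tested = False`` and missing statistics,
    preserving the distinction between untested and tested-null.
    """

    table: pd.DataFrame
    c_hat: float
    c_hat_se: float
    c_hat_p: float
    c_prime_hat: float
    alpha: float
    d: int
    S: np.ndarray  # indices with p_b < alpha
    method: str = "hdma"
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        sig = self.table["significant"].fillna(False).to_numpy(dtype=bool)
        return np.flatnonzero(sig)


def fit_total_effect(X, Y, covariates=None, family="binary"):
    """Marginal model of Y on X (+ covariates); returns (c_hat, se, p).

    Logistic regression for the binary family, OLS for the continuous one.
    """
    X = np.asarray(X, dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("exposure is constant; total effect inestimable")
    cols = [np.asarray(X, dtype=float)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        cols.append(C[:, None] if C.ndim == 1 else C)
    D = sm.add_constant(np.column_stack(cols))
    if family == "binary":
        fit = sm.GLM(np.asarray(Y, dtype=float), D, family=sm.families.Binomial()).fit()
    elif family == "continuous":
        fit = sm.OLS(np.asarray(Y, dtype=float), D).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def fit_alpha_path(M_t, X, covariates=None):
    """OLS of one mediator on the exposure; normal-reference p-value.

    Returns (a_hat, se_a, p_a) with p_a = 2(1 - Phi(|a_hat|/se_a)).
    """
    M_t = np.asarray(M_t, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("exposure is constant; a-path inestimable")
    cols = [X]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        cols.append(C[:, None] if C.ndim == 1 else C)
    D = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(M_t, D).fit()
    a_hat, se_a = float(fit.params[1]), float(fit.bse[1])
    p_a = float(2.0 * stats.norm.sf(abs(a_hat) / se_a)) if se_a > 0 else np.nan
    return a_hat, se_a, p_a


def _alpha_path_all(M, X, covariates=None):
    """Vectorised OLS a-path for every column of M (same design each time)."""
    n = len(X)
    cols = [np.ones(n), np.asarray(X, dtype=float)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        cols.extend((C[:, None] if C.ndim == 1 else C).T)
    D = np.column_stack(cols)
    Q, R = np.linalg.qr(D)
    coefs = np.linalg.solve(R, Q.T @ M)  # (q, k)
    resid = M - D @ coefs
    dof = n - D.shape[1]
    s2 = np.einsum("ij,ij->j", resid, resid) / dof
    xtx_inv_11 = np.linalg.inv(R.T @ R)[1, 1]
    se = np.sqrt(s2 * xtx_inv_11)
    a_hat = coefs[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = 2.0 * stats.norm.sf(np.abs(a_hat) / se)
    return a_hat, se, p_a


def joint_pvalue(p_a: float, p_b: float) -> float:
    """Intersection-union p-value: max of the two component p-values."""
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return max(p_a, p_b)


def effect_decomposition(a_hat: float, b_hat: float, c_hat: float):
    """Indirect effect ab = a_hat*b_hat and its percent of the total effect.

    pct = |ab| / |c_hat| * 100; reported as NaN when c_hat = 0.
    """
    ab = a_hat * b_hat
    if c_hat == 0:
        logger.warning("total effect is 0; percent of total effect undefined")
        return ab, float("nan")
    return ab, abs(ab) / abs(c_hat) * 100.0


def _adjusted(pvals, correction):
    if correction is None:
        return pvals
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method=correction)[1]


def hdma_test(X, M, Y, covariates=None, family="binary",
              config: TestConfig | None = None) -> MediationResult:
    """Run the full high-dimensional mediation testing pipeline on one dataset."""
    config = config or TestConfig()
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = M.shape
    if n < 10:
        raise ValueError(f"refusing to run with n={n} < 10 samples")

    d = screening.screening_dimension(n, config.sis_divisor)
    try:
        screen = screening.marginal_screen(
            M, X, Y, covariates=covariates, d=d,
            basis=config.sis_basis, family=family,
        )
    except Exception as err:  # pragma: no cover - stage tagging
        raise RuntimeError(f"screening stage failed: {err}") from err
    kept = np.sort(screen.kept)

    ncov = 0
    design_cols = [X[:, None]]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[:, None] if C.ndim == 1 else C
        ncov = C.shape[1]
        design_cols.append(C)
    design_cols.append(M[:, kept])
    design = np.column_stack(design_cols)
    unpen = np.zeros(design.shape[1], dtype=bool)
    unpen[: 1 + ncov] = True  # exposure and covariates are not selection targets

    lam = config.lambda_
    if lam is None:
        lam = "plugin" if family == "binary" else "cv"
    try:
        if family == "binary":
            fit = inference.debias_logistic(
                design, Y, lambda_=lam,
                nodewise_lambdas=config.nodewise_lambdas, unpenalized_mask=unpen,
            )
        else:
            fit = inference.debias_linear(
                design, Y, lambda_=lam,
                nodewise_lambdas=config.nodewise_lambdas, unpenalized_mask=unpen,
            )
    except Exception as err:
        raise RuntimeError(f"debiased inference stage failed: {err}") from err

    med_slice = slice(1 + ncov, None)
    b_hat = fit.estimates[med_slice]
    se_b = fit.se[med_slice]
    p_b = _adjusted(fit.pvalues[med_slice], config.correction)
    c_prime_hat = float(fit.estimates[0])

    a_hat, se_a, p_a = _alpha_path_all(M[:, kept], X, covariates)
    p_a = _adjusted(p_a, config.correction)

    c_hat, c_se, c_p = fit_total_effect(X, Y, covariates, family)

    p_joint = np.maximum(p_a, p_b)
    sig = (p_a < config.alpha) & (p_b < config.alpha)
    ab = a_hat * b_hat
    if c_hat != 0:
        pct = np.abs(ab) / abs(c_hat) * 100.0
    else:
        pct = np.full(ab.shape, np.nan)

    table = pd.DataFrame(
        {
            "mediator_id": np.arange(k),
            "tested": False,
            "a_hat": np.nan, "se_a": np.nan, "p_a": np.nan,
            "b_hat": np.nan, "se_b": np.nan, "p_b": np.nan,
            "ab": np.nan, "pct_total_effect": np.nan,
            "p_joint": np.nan, "significant": pd.array([pd.NA] * k, dtype="boolean"),
        }
    )
    table.loc[kept, "tested"] = True
    table.loc[kept, ["a_hat", "se_a", "p_a"]] = np.column_stack([a_hat, se_a, p_a])
    table.loc[kept, ["b_hat", "se_b", "p_b"]] = np.column_stack([b_hat, se_b, p_b])
    table.loc[kept, "ab"] = ab
    table.loc[kept, "pct_total_effect"] = pct
    table.loc[kept, "p_joint"] = p_joint
    table.loc[kept, "significant"] = sig

    return MediationResult(
        table=table,
        c_hat=c_hat,
        c_hat_se=c_se,
        c_hat_p=c_p,
        c_prime_hat=c_prime_hat,
        alpha=config.alpha,
        d=d,
        S=kept[p_b < config.alpha],
        method="hdma",
        details={
            "lambda": fit.lasso.lambda_,
            "sigma_eps": fit.sigma_eps,
            "sis_basis": config.sis_basis,
            "sis_divisor": config.sis_divisor,
            "kept": kept,
            "screen_scores": screen.scores,
            "screen_ranked": screen.ranked_indices,
            "b_lasso": fit.lasso.coefficients[med_slice],
        },
    )
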