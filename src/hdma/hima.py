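"""HIMA-style comparator: SIS -> MCP selection -> refit -> joint test.

The comparator pipeline selects mediators with a minimax concave penalty
(MCP) on the outcome model, refits the survivors by ordinary (unpenalized)
regression to obtain Wald p-values p_b, and combines them with the OLS
exposure->mediator p-values p_a through the same max-p joint-significance
rule as the main method.  Refit p-values ignore the preceding selection
step; that post-selection optimism is a property of the comparator being
reproduced, not corrected here.

The MCP coordinate update has the firm-threshold closed form: with
coordinate curvature v and univariate least-squares score z,

    b = S(z, lambda) / (v - 1/gamma)   if |z| <= v * gamma * lambda,
    b = z / v                          otherwise,

which for v = 1 (orthonormal design) leaves |b| > gamma*lambda unshrunk.
For the logistic family, where v < 1/gamma is possible, the concavity is
adaptively rescaled per coordinate (gamma_eff = gamma / v) so every
univariate problem stays convex — the rescaling device of the reference
coordinate-descent literature for nonconvex GLM penalties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import screening
from ._solvers import solve_penalized_quadratic
from .inference import _expit, _standardize
from .mediation import (
    MediationResult,
    TestConfig,
    _adjusted,
    _alpha_path_all,
    fit_total_effect,
)

logger = logging.getLogger(__name__)

__all__ = ["McpFit", "fit_mcp", "mcp_path_bic", "hima_test"]

_N_LAMBDA_BIC = 50
_LAMBDA_MIN_RATIO = 0.01
_CD_TOL = 1e-10
_CD_MAX_PASSES = 10_000
_IRLS_MAX = 40
_MM_MAX = 1000
_MM_TOL = 1e-6


@dataclass(frozen=True)
class McpFit:
    """MCP-penalized fit; ``selected`` are indices with nonzero coefficients."""

    coefficients: np.ndarray
    intercept: float
    lambda_: float
    gamma: float
    family: str
    selected: np.ndarray


def fit_mcp(design, response, lambda_, gamma=3.0, family="continuous",
            unpenalized_mask=None):
    """MCP-penalized regression with selected columns exempt from the penalty.

    Linear family: coordinate descent on the exact quadratic.  Binary
    family: IRLS, each step solving the weighted quadratic subproblem by
    the same coordinate descent.  Columns are standardized internally;
    coefficients are returned on the original scale.
    """
    fit, _ = _fit_mcp_warm(design, response, lambda_, gamma, family,
                           unpenalized_mask)
    return fit


def _fit_mcp_warm(design, response, lambda_, gamma=3.0, family="continuous",
                  unpenalized_mask=None, _warm=None):
    if gamma <= 1.0:
        raise ValueError("gamma must exceed 1")
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    mask = np.zeros(p, dtype=bool) if unpenalized_mask is None else np.asarray(
        unpenalized_mask, dtype=bool
    )
    Xs, mu, sd = _standardize(X)
    # leading coordinate is the (unpenalized) intercept
    penfac = np.concatenate([[0.0], (~mask).astype(float)])
    D = np.column_stack([np.ones(n), Xs])
    beta = np.zeros(p + 1) if _warm is None else _warm.copy()
    if family == "continuous":
        H = D.T @ D / n
        q = D.T @ y / n
        beta = solve_penalized_quadratic(H, q, lambda_, gamma, penfac, beta,
                                         tol=_CD_TOL, max_passes=_CD_MAX_PASSES)
    elif family == "binary":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("binary family requires a 0/1 response")
        if _warm is None:
            ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
            beta[0] = math.log(ybar / (1 - ybar))
        # IRLS first (fast when it settles); under a nonconvex penalty IRLS
        # can cycle between active sets, so fall back to majorize-minimize
        # with the global curvature bound w <= 1/4, which descends
        # monotonically at the cost of more (cheap, warm-started) iterations
        converged = False
        for _ in range(_IRLS_MAX):
            eta = D @ beta
            pr = _expit(eta)
            w = np.maximum(pr * (1 - pr), 1e-5)
            H = D.T @ (D * w[:, None]) / n
            q = D.T @ (w * eta + (y - pr)) / n
            old = beta.copy()
            beta = solve_penalized_quadratic(H, q, lambda_, gamma, penfac, beta,
                                             tol=_CD_TOL, max_passes=_CD_MAX_PASSES)
            if np.abs(beta).max() > 1e4:
                raise FloatingPointError(
                    "MCP logistic fit diverged (possible separation)"
                )
            if np.abs(beta - old).max() < _MM_TOL:
                converged = True
                break
        if not converged:
            H = D.T @ D / (4.0 * n)
            for _ in range(_MM_MAX):
                eta = D @ beta
                pr = _expit(eta)
                grad = D.T @ (pr - y) / n
                q = H @ beta - grad
                old = beta.copy()
                beta = solve_penalized_quadratic(
                    H, q, lambda_, gamma, penfac, beta,
                    tol=_CD_TOL, max_passes=_CD_MAX_PASSES,
                )
                if np.abs(beta - old).max() < _MM_TOL:
                    break
            else:
                logger.warning(
                    "MCP MM fallback hit max iterations at lambda=%.3e", lambda_
                )
    else:
        raise ValueError(f"unknown family {family!r}")
    coef = beta[1:] / sd
    intercept = float(beta[0] - mu @ coef)
    return McpFit(
        coefficients=coef,
        intercept=intercept,
        lambda_=float(lambda_),
        gamma=float(gamma),
        family=family,
        selected=np.flatnonzero(coef != 0),
    ), beta


def _bic(X, y, fit: McpFit, family):
    n = len(y)
    eta = X @ fit.coefficients + fit.intercept
    df = 1 + np.count_nonzero(fit.coefficients)
    if family == "continuous":
        rss = float(np.sum((y - eta) ** 2))
        return n * math.log(max(rss, 1e-300) / n) + math.log(n) * df
    pr = np.clip(_expit(eta), 1e-10, 1 - 1e-10)
    dev = -2.0 * float(np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
    return dev + math.log(n) * df


def mcp_path_bic(design, response, gamma=3.0, family="continuous",
                 unpenalized_mask=None, n_lambda=_N_LAMBDA_BIC, dfmax=None):
    """Fit an MCP path on a geometric lambda grid and pick the BIC minimiser.

    The path stops early once the active set exceeds ``dfmax`` (default
    n/3): BIC never selects such dense fits and the nonconvex coordinate
    descent becomes unstable there.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to fit")
    n = len(y)
    Xs, _, _ = _standardize(X)
    r = y - y.mean()
    mask = np.zeros(X.shape[1], dtype=bool) if unpenalized_mask is None else np.asarray(
        unpenalized_mask, dtype=bool
    )
    lam_max = np.abs(Xs[:, ~mask].T @ r).max() / n
    grid = np.geomspace(lam_max, lam_max * _LAMBDA_MIN_RATIO, n_lambda)
    if dfmax is None:
        dfmax = max(n // 3, 10)
    best, best_bic = None, np.inf
    warm = None
    for lam in grid:
        try:
            fit, warm = _fit_mcp_warm(X, y, lam, gamma, family, mask, _warm=warm)
        except (RuntimeError, FloatingPointError) as err:
            logger.warning("MCP path stopped at lambda=%.3e: %s", lam, err)
            break
        b = _bic(X, y, fit, family)
        if b < best_bic:
            best, best_bic = fit, b
        if len(fit.selected) > dfmax:
            break
    if best is None:
        raise RuntimeError("MCP path failed at every lambda")
    return best


def hima_test(X, M, Y, covariates=None, family="binary",
              config: TestConfig | None = None, gamma=3.0) -> MediationResult:
    """SIS -> MCP selection -> unpenalized refit -> max-p joint test."""
    from .mediation import RESULT_COLUMNS  # shared schema

    config = config or TestConfig()
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = M.shape
    if n < 10:
        raise ValueError(f"refusing to run with n={n} < 10 samples")

    d = screening.screening_dimension(n, config.sis_divisor)
    screen = screening.marginal_screen(
        M, X, Y, covariates=covariates, d=d, basis=config.sis_basis, family=family
    )
    kept = np.sort(screen.kept)

    ncov = 0
    cols = [X[:, None]]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C[:, None] if C.ndim == 1 else C
        ncov = C.shape[1]
        cols.append(C)
    cols.append(M[:, kept])
    design = np.column_stack(cols)
    unpen = np.zeros(design.shape[1], dtype=bool)
    unpen[: 1 + ncov] = True

    mcp = mcp_path_bic(design, Y, gamma=gamma, family=family, unpenalized_mask=unpen)
    med_coef = mcp.coefficients[1 + ncov:]
    surv_local = np.flatnonzero(med_coef != 0)  # positions within kept
    survivors = kept[surv_local]

    # unpenalized refit on the survivors for Wald p-values
    b_hat = np.full(len(kept), np.nan)
    se_b = np.full(len(kept), np.nan)
    p_b = np.full(len(kept), np.nan)
    c_prime_hat = float(mcp.coefficients[0])
    if len(survivors):
        refit_cols = [np.ones(n), X]
        if covariates is not None:
            refit_cols.append(C)
        refit_cols.append(M[:, survivors])
        D = np.column_stack(refit_cols)
        if family == "binary":
            refit = sm.GLM(Y, D, family=sm.families.Binomial()).fit()
        else:
            refit = sm.OLS(Y, D).fit()
        off = 2 + ncov
        b_hat[surv_local] = refit.params[off:]
        se_b[surv_local] = refit.bse[off:]
        p_b[surv_local] = _adjusted(np.asarray(refit.pvalues[off:]), config.correction)
        c_prime_hat = float(refit.params[1])

    a_hat, se_a, p_a = _alpha_path_all(M[:, kept], X, covariates)
    p_a = _adjusted(p_a, config.correction)
    c_hat, c_se, c_p = fit_total_effect(X, Y, covariates, family)

    with np.errstate(invalid="ignore"):
        p_joint = np.maximum(p_a, p_b)
        sig = (p_a < config.alpha) & (p_b < config.alpha)
    sig = np.where(np.isnan(p_b), False, sig).astype(bool)
    ab = a_hat * b_hat
    pct = np.abs(ab) / abs(c_hat) * 100.0 if c_hat != 0 else np.full(ab.shape, np.nan)

    table = pd.DataFrame(
        {
            "mediator_id": np.arange(k),
            "tested": False,
            "a_hat": np.nan, "se_a": np.nan, "p_a": np.nan,
            "b_hat": np.nan, "se_b": np.nan, "p_b": np.nan,
            "ab": np.nan, "pct_total_effect": np.nan,
            "p_joint": np.nan, "significant": pd.array([pd.NA] * k, dtype="boolean"),
        }
    )[RESULT_COLUMNS]
    table.loc[kept, "tested"] = True
    table.loc[kept, ["a_hat", "se_a", "p_a"]] = np.column_stack([a_hat, se_a, p_a])
    table.loc[kept, ["b_hat", "se_b", "p_b"]] = np.column_stack([b_hat, se_b, p_b])
    table.loc[kept, "ab"] = ab
    table.loc[kept, "pct_total_effect"] = pct
    table.loc[kept, "p_joint"] = p_joint
    table.loc[kept, "significant"] = sig

    S = survivors[p_b[surv_local] < config.alpha] if len(survivors) else np.array([], int)
    return MediationResult(
        table=table,
        c_hat=c_hat,
        c_hat_se=c_se,
        c_hat_p=c_p,
        c_prime_hat=c_prime_hat,
        alpha=config.alpha,
        d=d,
        S=S,
        method="hima",
        details={
            "lambda": mcp.lambda_,
            "gamma": mcp.gamma,
            "sis_basis": config.sis_basis,
            "sis_divisor": config.sis_divisor,
            "kept": kept,
            "screen_scores": screen.scores,
            "screen_ranked": screen.ranked_indices,
            "mcp_survivors": survivors,
        },
    )
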