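"""Sure independence screening (SIS) of mediators.

Reduces the mediator dimension from ultra-high to high by ranking mediators
on a marginal association statistic and retaining the top
d = ceil(n / (divisor * ln n)).  Screening can be based on the outcome
model (Y ~ X + M_j, score |b_j|/se, the default) or the mediator model
(M_j ~ X, score |a_j|/se).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "screening_dimension", "marginal_screen"]

_BASES = ("outcome_model", "mediator_model")


@dataclass(frozen=True)
class ScreenResult:
    """Ranked mediators and the retained top-d set.

    ``kept`` is the first ``len(kept)`` entries of ``ranked_indices``; ranking
    is by decreasing score with ties broken by ascending original index.
    """

    ranked_indices: np.ndarray
    scores: np.ndarray
    kept: np.ndarray
    d: int
    basis: str


def screening_dimension(n: int, divisor: float = 1.0) -> int:
    """Retained dimension d = ceil(n / (divisor * ln n)).

    ``divisor`` is 1 for the standard rule n/log(n) and 2 for the more
    aggressive n/(2 log n) reduction used when d must stay small.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    if n <= math.e:
        raise ValueError(f"n must exceed e for the n/log(n) rule, got {n}")
    return int(math.ceil(n / (divisor * math.log(n))))


def _as_base_design(n: int, X: np.ndarray, covariates) -> np.ndarray:
    cols = [np.ones(n), np.asarray(X, dtype=float)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates row count does not match n")
        cols.extend(C.T)
    return np.column_stack(cols)


def _ols_tstats(B: np.ndarray, V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|t|-statistics of each column of V added separately to OLS of y on B.

    Vectorised via Frisch-Waugh: residualise y and each candidate column on
    the base design, then the added-variable slope is a univariate OLS.
    Constant (residually) columns score 0.
    """
    n, q = B.shape
    Q, _ = np.linalg.qr(B)
    ry = y - Q @ (Q.T @ y)
    RV = V - Q @ (Q.T @ V)
    ss = np.einsum("ij,ij->j", RV, RV)
    dof = n - q - 1
    scores = np.zeros(V.shape[1])
    ok = ss > 1e-12 * n
    if not np.all(ok):
        logger.warning("%d constant/collinear mediator columns scored 0", (~ok).sum())
    beta = np.zeros(V.shape[1])
    beta[ok] = (RV[:, ok] * ry[:, None]).sum(axis=0) / ss[ok]
    rss = (ry @ ry) - beta**2 * ss
    rss = np.maximum(rss, 1e-12)
    se = np.sqrt(rss / dof / np.maximum(ss, 1e-300))
    scores[ok] = np.abs(beta[ok]) / se[ok]
    return scores


def _logistic_tstats(B: np.ndarray, V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|z|-statistics of V_j in logistic fits y ~ B + V_j, vectorised over j.

    Runs Newton-Raphson simultaneously for all k single-mediator logistic
    regressions (each has q+1 parameters).  Non-converged or separated fits
    score 0 with a warning rather than failing the screen.
    """
    n, q = B.shape
    k = V.shape[1]
    p_dim = q + 1
    beta = np.zeros((k, p_dim))
    # initialise intercept at the logit of the outcome prevalence
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[:, 0] = math.log(ybar / (1 - ybar))
    ok = np.ones(k, dtype=bool)
    eye = np.eye(p_dim) * 1e-10
    for _ in range(40):
        eta = B @ beta[:, :q].T + V * beta[:, q]  # (n, k)
        np.clip(eta, -30, 30, out=eta)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        # gradient (k, p_dim)
        g = np.empty((k, p_dim))
        g[:, :q] = r.T @ B
        g[:, q] = np.einsum("ij,ij->j", r, V)
        # Hessian blocks (k, p_dim, p_dim)
        H = np.empty((k, p_dim, p_dim))
        H[:, :q, :q] = np.einsum("ij,iq,ir->jqr", w, B, B)
        HBv = np.einsum("ij,iq,ij->jq", w, B, V)
        H[:, :q, q] = HBv
        H[:, q, :q] = HBv
        H[:, q, q] = np.einsum("ij,ij,ij->j", w, V, V)
        try:
            step = np.linalg.solve(H + eye, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + np.eye(p_dim) * 1e-6, g[..., None])[..., 0]
        np.clip(step, -5, 5, out=step)
        beta += step
        if np.abs(step).max() < 1e-8:
            break
    # final weights for standard errors
    eta = B @ beta[:, :q].T + V * beta[:, q]
    np.clip(eta, -30, 30, out=eta)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    H = np.empty((k, p_dim, p_dim))
    H[:, :q, :q] = np.einsum("ij,iq,ir->jqr", w, B, B)
    HBv = np.einsum("ij,iq,ij->jq", w, B, V)
    H[:, :q, q] = HBv
    H[:, q, :q] = HBv
    H[:, q, q] = np.einsum("ij,ij,ij->j", w, V, V)
    scores = np.zeros(k)
    for j in range(k):
        try:
            cov = np.linalg.inv(H[j] + eye)
        except np.linalg.LinAlgError:
            ok[j] = False
            continue
        se = math.sqrt(max(cov[q, q], 0.0))
        if not np.isfinite(se) or se <= 0 or abs(beta[j, q]) > 50:
            ok[j] = False
            continue
        scores[j] = abs(beta[j, q]) / se
    if not np.all(ok):
        logger.warning(
            "%d mediator columns scored 0 in logistic screening "
            "(separation or degenerate fit)",
            int((~ok).sum()),
        )
        scores[~ok] = 0.0
    return scores


def marginal_screen(
    M: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    covariates=None,
    d: int = None,
    basis: str = "outcome_model",
    family: str = "binary",
) -> ScreenResult:
    """Rank mediators marginally and keep the top d.

    basis="outcome_model" scores mediator j by the standardised coefficient
    |b_j|/se in the single-mediator outcome regression Y ~ X + M_j
    (+ covariates), in the stated family; basis="mediator_model" scores
    |a_j|/se from the linear regression M_j ~ X (+ covariates).
    """
    M = np.asarray(M, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = M.shape
    if X.shape[0] != n or Y.shape[0] != n:
        raise ValueError("X, Y, M have inconsistent sample counts")
    if d is None or d < 1:
        raise ValueError("d must be a positive integer")
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")

    B = _as_base_design(n, X, covariates)
    if basis == "mediator_model":
        # score the X coefficient in M_j ~ 1 (+cov) + X for every j:
        # residualise X and all M_j on the intercept(+cov) design at once
        B0 = np.delete(B, 1, axis=1)  # base without X
        Q, _ = np.linalg.qr(B0)
        rx = X - Q @ (Q.T @ X)
        RM = M - Q @ (Q.T @ M)
        sxx = rx @ rx
        if sxx <= 1e-12 * n:
            raise ValueError("exposure is constant; mediator-model screen undefined")
        a_hat = RM.T @ rx / sxx
        rss = np.einsum("ij,ij->j", RM, RM) - a_hat**2 * sxx
        dof = n - B0.shape[1] - 1
        se = np.sqrt(np.maximum(rss, 1e-12) / dof / sxx)
        scores = np.abs(a_hat) / se
        const = RM.std(axis=0) <= 1e-10
        if const.any():
            logger.warning("%d constant mediator columns scored 0", const.sum())
            scores[const] = 0.0
    elif family == "continuous":
        scores = _ols_tstats(B, M, Y)
    elif family == "binary":
        scores = _logistic_tstats(B, M, Y)
    else:
        raise ValueError(f"unknown family {family!r}")

    # stable sort on (-score, index): ties broken by ascending original index
    order = np.lexsort((np.arange(k), -scores))
    kept = order[: min(d, k)]
    return ScreenResult(
        ranked_indices=order,
        scores=scores,
        kept=kept,
        d=int(d),
        basis=basis,
    )
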