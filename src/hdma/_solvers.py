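"""Coordinate-descent kernel for penalized quadratic programs.

Solves  min_b  0.5 b'Hb - q'b + sum_j penfac_j * P(b_j; lam, gamma)
where P is the MCP penalty (soft/firm thresholding); gamma = inf gives the
LASSO.  H is a Gram-type curvature matrix (X'X/n or X'WX/n), so each
coordinate update is O(p) and reweighting or refitting only costs one new
Gram.  Unpenalized coordinates carry penfac = 0.  The MCP concavity is
rescaled by the coordinate curvature v (gamma_eff = gamma / v) so every
univariate update stays convex for gamma > 1 (adaptive rescaling).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cd_penalized_quadratic(H, q, lam, gamma, penfac, beta, tol, max_passes):
    """In-place coordinate descent; returns #passes, or -1 on non-convergence."""
    p = q.shape[0]
    r = q - H @ beta
    for it in range(max_passes):
        dmax = 0.0
        for j in range(p):
            v = H[j, j]
            if v <= 1e-300:
                continue
            z = r[j] + v * beta[j]
            l = lam * penfac[j]
            if l <= 0.0:
                new = z / v
            else:
                az = abs(z)
                if az <= l:
                    new = 0.0
                elif az <= v * gamma * l:
                    # firm threshold; gamma=inf reduces to soft threshold
                    new = (az - l) / (v * (1.0 - 1.0 / gamma))
                    if z < 0.0:
                        new = -new
                else:
                    new = z / v
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                for i in range(p):
                    r[i] -= H[i, j] * d
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        if dmax < tol:
            return it + 1
    return -1


def solve_penalized_quadratic(H, q, lam, gamma, penfac, beta0=None,
                              tol=1e-9, max_passes=100_000):
    """Wrapper allocating/validating; raises on non-convergence."""
    q = np.ascontiguousarray(q, dtype=np.float64)
    H = np.ascontiguousarray(H, dtype=np.float64)
    beta = np.zeros(q.shape[0]) if beta0 is None else np.asarray(
        beta0, dtype=np.float64
    ).copy()
    penfac = np.ascontiguousarray(penfac, dtype=np.float64)
    status = cd_penalized_quadratic(H, q, float(lam), float(gamma), penfac,
                                    beta, float(tol), int(max_passes))
    if status < 0:
        raise RuntimeError(
            f"coordinate descent did not converge in {max_passes} passes "
            f"(lambda={lam:.4e}, gamma={gamma})"
        )
    return beta
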