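"""Numba kernels for the partially penalised weighted-lasso solver.

The optimisation problem is

    min_{α,β}  ‖y − Uα − Nβ‖² + λ Σ_j w_j |β_j|

solved by block coordinate descent: an exact least-squares update of the
unpenalised block α given β (via a precomputed pseudoinverse of U), then one
soft-thresholding pass over the penalised coordinates, iterated until the
objective change falls below tolerance.  The objective is monotone
non-increasing across sweeps; the kernel reports a flag if that is ever
violated beyond round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _soft(c, thr):
    if c > thr:
        return c - thr
    if c < -thr:
        return c + thr
    return 0.0


@njit(cache=True)
def cd_path(U, P, N, y, w, lam_path, tol, max_iter):
    """Block coordinate descent along a descending penalty path.

    Parameters
    ----------
    U : (n, t) unpenalised design block.
    P : (t, n) pseudoinverse of U (exact LS update operator for α).
    N : (n, q) penalised design block.
    y : (n,) outcome.
    w : (q,) nonnegative penalty weights.
    lam_path : (L,) penalties, scanned in the order given (warm starts).
    tol : objective-change convergence tolerance (relative).
    max_iter : sweep budget per penalty value.

    Returns
    -------
    alphas : (L, t), betas : (L, q), n_iters : (L,), objs : (L,),
    monotone_ok : (L,) 1 if the objective never increased beyond round-off,
    converged : (L,) 1 if the sweep budget was not exhausted.
    """
    n, t = U.shape
    q = N.shape[1]
    L = lam_path.shape[0]

    col_ss = np.empty(q)
    for j in range(q):
        s = 0.0
        for i in range(n):
            s += N[i, j] * N[i, j]
        col_ss[j] = s

    alphas = np.zeros((L, t))
    betas = np.zeros((L, q))
    n_iters = np.zeros(L, dtype=np.int64)
    objs = np.zeros(L)
    monotone_ok = np.ones(L, dtype=np.int64)
    converged = np.zeros(L, dtype=np.int64)

    beta = np.zeros(q)
    alpha = P @ y
    r = y - U @ alpha

    for l in range(L):
        lam = lam_path[l]
        pen = 0.0
        for j in range(q):
            pen += w[j] * abs(beta[j])
        prev_obj = r @ r + lam * pen

        for it in range(max_iter):
            # exact LS update of the unpenalised block
            dalpha = P @ r
            alpha += dalpha
            r -= U @ dalpha

            # one soft-thresholding sweep over penalised coordinates
            for j in range(q):
                if col_ss[j] <= 0.0:
                    continue
                bj = beta[j]
                c = 0.0
                for i in range(n):
                    c += N[i, j] * r[i]
                c += col_ss[j] * bj
                bnew = _soft(c, 0.5 * lam * w[j]) / col_ss[j]
                if bnew != bj:
                    d = bj - bnew
                    for i in range(n):
                        r[i] += N[i, j] * d
                    beta[j] = bnew

            pen = 0.0
            for j in range(q):
                pen += w[j] * abs(beta[j])
            obj = r @ r + lam * pen

            if obj > prev_obj + 1e-8 * (1.0 + abs(prev_obj)):
                monotone_ok[l] = 0
            if prev_obj - obj <= tol * (1.0 + abs(obj)):
                prev_obj = obj
                n_iters[l] = it + 1
                converged[l] = 1
                break
            prev_obj = obj
        else:
            n_iters[l] = max_iter

        alphas[l] = alpha
        betas[l] = beta
        objs[l] = prev_obj

    return alphas, betas, n_iters, objs, monotone_ok, converged


def warm_up() -> None:
    """Trigger JIT compilation on a toy problem (import-time optional)."""
    U = np.ones((4, 1))
    P = np.full((1, 4), 0.25)
    N = np.arange(8.0).reshape(4, 2)
    y = np.arange(4.0)
    cd_path(U, P, N, y, np.ones(2), np.array([0.1]), 1e-10, 10)
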