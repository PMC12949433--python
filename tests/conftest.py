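"""Shared fixtures and independent solver oracles used across the suite."""

import itertools

import numpy as np
import pytest

from hublasso import ExpressionMatrix


@pytest.fixture()
def rng():
    # fresh stream per test so problems are order-independent
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_expression(rng):
    """Small well-conditioned expression matrix (n=40, p=6)."""
    base = rng.standard_normal((40, 6))
    base[:, 1] += 0.5 * base[:, 0]
    return ExpressionMatrix(
        base,
        [f"P{j}" for j in range(6)],
        [f"s{i}" for i in range(40)],
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately different algorithms from the package)
# ---------------------------------------------------------------------------

def admm_glasso(S, lam, rho=1.0, n_iter=5000, tol=1e-12):
    """ADMM solver for the graphical lasso (off-diagonal ℓ1 penalty).

    Splitting X = Z with an eigenvalue prox for the log-det term and
    soft-thresholding for the penalty; independent of the coordinate-descent
    route used by the package.
    """
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(n_iter):
        W = rho * (Z - U) - S
        vals, vecs = np.linalg.eigh(W)
        xvals = (vals + np.sqrt(vals**2 + 4 * rho)) / (2 * rho)
        X = (vecs * xvals) @ vecs.T
        Z_old = Z
        A = X + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U += X - Z
        if max(np.abs(X - Z).max(), np.abs(Z - Z_old).max()) < tol:
            break
    return Z


def glasso_objective(S, theta, lam):
    """Penalised log-likelihood basis log det Θ − tr(SΘ) − λ‖Θ‖₁,offdiag."""
    sign, logdet = np.linalg.slogdet(theta)
    assert sign > 0
    off = theta.copy()
    np.fill_diagonal(off, 0.0)
    return logdet - np.sum(S * theta) - lam * np.abs(off).sum()


def exact_partial_lasso(U, N, y, lam, w, tol=1e-9):
    """Global minimiser of ‖y−Uα−Nβ‖² + λ Σ w_j|β_j| by support enumeration.

    For every candidate active set and sign pattern the stationary point is a
    linear solve; the unique pattern whose solution satisfies all KKT
    conditions is the global optimum of this convex problem.  Exponential in
    q — use only on tiny instances.
    """
    U = np.atleast_2d(U)
    n, t = U.shape
    q = N.shape[1]
    best = None
    for active in itertools.chain.from_iterable(
        itertools.combinations(range(q), k) for k in range(q + 1)
    ):
        for signs in itertools.product((-1.0, 1.0), repeat=len(active)):
            D = np.column_stack([U, N[:, list(active)]]) if active else U
            c = np.concatenate([np.zeros(t), lam * np.array(signs) * w[list(active)] / 2.0])
            try:
                theta = np.linalg.solve(D.T @ D, D.T @ y - c[: D.shape[1]])
            except np.linalg.LinAlgError:
                continue
            alpha, beta_a = theta[:t], theta[t:]
            if any(s * b <= 0 for s, b in zip(signs, beta_a)):
                continue
            beta = np.zeros(q)
            beta[list(active)] = beta_a
            r = y - U @ alpha - N @ beta
            inactive = [j for j in range(q) if j not in active]
            if any(abs(2 * N[:, j] @ r) > lam * w[j] + tol for j in inactive):
                continue
            obj = float(r @ r + lam * np.sum(w * np.abs(beta)))
            if best is None or obj < best[0] - 1e-12:
                best = (obj, alpha, beta)
    assert best is not None, "no KKT-consistent pattern found"
    return best
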