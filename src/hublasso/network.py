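"""Sparse Gaussian graphical model estimation for protein co-expression networks.

A Gaussian graphical model (GGM) encodes conditional dependencies between
proteins in the zeros of the precision matrix Θ = Σ⁻¹.  The graphical lasso
estimates a sparse Θ by maximising the ℓ1-penalised log-likelihood

    log det(Θ) − tr(Σ̂Θ) − λ Σ_{j≠k} |θ_jk|,

where the penalty is applied to off-diagonal entries only.  The penalty λ is
chosen by the extended Bayesian information criterion (eBIC),

    eBIC(λ) = −2ℓ(Θ̂λ) + E log(n) + 4γE log(p),

with E the number of edges and γ ∈ [0, 1] a sparsity hyperparameter (γ = 0
recovers the ordinary BIC).  Off-diagonal entries of Θ̂ are converted to
partial correlations ρ̂_jk = −θ̂_jk / √(θ̂_jj θ̂_kk), which form the weighted
adjacency matrix of the estimated network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidPrecisionError

try:  # warm-startable variant (same solver the public function wraps)
    from sklearn.covariance._graph_lasso import _graphical_lasso

    def _glasso(emp_cov, alpha, cov_init, tol, max_iter):
        cov, prec, _costs, n_iter = _graphical_lasso(
            emp_cov, alpha, cov_init=cov_init, tol=tol, max_iter=max_iter
        )
        return cov, prec, n_iter

except ImportError:  # pragma: no cover - fallback if private API moves
    from sklearn.covariance import graphical_lasso as _public_glasso

    def _glasso(emp_cov, alpha, cov_init, tol, max_iter):
        cov, prec, n_iter = _public_glasso(
            emp_cov, alpha, tol=tol, max_iter=max_iter, return_n_iter=True
        )
        return cov, prec, n_iter


#: entries of Θ̂ with magnitude at or below this value count as absent edges;
#: the coordinate solver produces exact zeros, the threshold only guards
#: against numerical dust from the final matrix inversion.
EDGE_TOL = 1e-10


@dataclass
class ExpressionMatrix:
    """An n × p matrix of protein abundances (samples in rows).

    Feature names must be unique, the payload must be fully observed, and at
    least three samples over two proteins are required.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, p = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 proteins, got {p}")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PrecisionEstimate:
    """A graphical-lasso precision estimate Θ̂ with its selection metadata.

    ``loglik_basis`` feeds :func:`ebic_score`; ``objective`` is the attained
    value of the penalised estimation objective (a solver diagnostic);
    ``ebic_value`` and ``gamma`` are NaN until the fit has been scored.
    """

    theta: np.ndarray
    lambda_used: float
    ebic_value: float = float("nan")
    gamma: float = float("nan")
    n_edges: int = 0
    #: per-sample Gaussian log-likelihood basis log det Θ̂ − tr(Σ̂Θ̂)
    #: (used by eBIC; constants dropped)
    loglik_basis: float = float("nan")
    #: attained penalised objective log det Θ̂ − tr(Σ̂Θ̂) − λ‖Θ̂‖₁,offdiag
    #: (solver diagnostic)
    objective: float = float("nan")
    n_iter: int = 0
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if not np.allclose(theta, theta.T, atol=1e-8):
            raise InvalidPrecisionError("precision estimate is not symmetric")
        self.theta = (theta + theta.T) / 2.0


@dataclass
class PartialCorrelationNetwork:
    """Symmetric p × p partial-correlation matrix; diagonal zero by convention."""

    rho: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape[0] != rho.shape[1]:
            raise ValueError("rho must be square")
        if len(self.feature_names) != rho.shape[0]:
            raise ValueError("feature_names length does not match rho")
        if not np.allclose(rho, rho.T, atol=1e-8):
            raise ValueError("rho must be symmetric")
        if np.any(np.abs(np.diag(rho)) > 0):
            raise ValueError("rho diagonal must be zero")
        if np.any(np.abs(rho) > 1 + 1e-8):
            raise ValueError("partial correlations must lie in [-1, 1]")
        self.rho = rho

    @property
    def n_features(self) -> int:
        return self.rho.shape[0]

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangular nonzero entries as a tidy edge table."""
        p = self.n_features
        iu, ju = np.triu_indices(p, k=1)
        mask = np.abs(self.rho[iu, ju]) > 0
        return pd.DataFrame(
            {
                "protein_a": [self.feature_names[i] for i in iu[mask]],
                "protein_b": [self.feature_names[j] for j in ju[mask]],
                "partial_correlation": self.rho[iu, ju][mask],
            }
        )


def empirical_covariance(x: ExpressionMatrix, center: bool = True) -> np.ndarray:
    """Maximum-likelihood covariance of the columns of ``x`` (divisor n)."""
    v = x.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 samples for a covariance")
    if center:
        v = v - v.mean(axis=0)
    return v.T @ v / v.shape[0]


def _count_edges(theta: np.ndarray) -> int:
    off = np.triu(theta, k=1)
    return int(np.sum(np.abs(off) > EDGE_TOL))


def _objectives(S: np.ndarray, theta: np.ndarray, lam: float) -> tuple[float, float]:
    """(Gaussian log-likelihood basis, penalised objective) of an estimate."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise InvalidPrecisionError("precision estimate is not positive definite")
    off = theta.copy()
    np.fill_diagonal(off, 0.0)
    basis = float(logdet - np.sum(S * theta))
    return basis, basis - lam * float(np.abs(off).sum())


#: largest acceptable stationarity violation (correlation scale) for a fit
#: whose dual-gap convergence flag failed; sklearn's gap estimate can stall
#: at a spurious constant even when the iterates have stopped moving.
KKT_ACCEPT = 0.05


def graphical_lasso_fit(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 200,
    cov_init: np.ndarray | None = None,
    kkt_accept: float = KKT_ACCEPT,
) -> PrecisionEstimate:
    """Solve the graphical lasso at a single penalty value.

    Parameters
    ----------
    S : ndarray
        Empirical covariance (symmetric PSD).
    lam : float
        Nonnegative ℓ1 penalty on off-diagonal precision entries.
    tol : float
        Duality-gap convergence tolerance of the coordinate solver.
    max_iter : int
        Maximum number of solver sweeps.
    cov_init : ndarray, optional
        Warm-start covariance (used when scanning a penalty path).

    Raises
    ------
    ValueError
        If ``lam`` is negative or ``S`` is not symmetric.
    ConvergenceError
        If the solver does not converge within ``max_iter`` sweeps.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError(f"penalty must be nonnegative, got {lam}")
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be square symmetric")

    if lam == 0:
        # unpenalised MLE; requires a well-conditioned covariance
        theta = np.linalg.inv(S)
        theta = (theta + theta.T) / 2.0
        fit = PrecisionEstimate(
            theta=theta, lambda_used=0.0, n_edges=_count_edges(theta), covariance=S
        )
        fit.loglik_basis, fit.objective = _objectives(S, theta, 0.0)
        return fit

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cov, prec, n_iter = _glasso(S, lam, cov_init, tol, max_iter)
        except FloatingPointError as exc:
            raise ConvergenceError(
                f"graphical lasso failed at lambda={lam:g}: {exc}",
                n_iter=max_iter,
                fatal=True,
            ) from exc
    gap_failed = any("did not converge" in str(w.message) for w in caught)

    prec = (prec + prec.T) / 2.0
    prec[np.abs(prec) <= EDGE_TOL] = 0.0
    fit = PrecisionEstimate(
        theta=prec,
        lambda_used=float(lam),
        n_edges=_count_edges(prec),
        n_iter=int(n_iter),
        covariance=cov,
    )
    if gap_failed:
        # the gap flag is unreliable; accept the fit iff it satisfies the
        # stationarity conditions to a reasonable numerical tolerance
        try:
            viol = kkt_violation(S, fit)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"graphical lasso produced a singular estimate at lambda={lam:g}",
                n_iter=n_iter,
            ) from exc
        if viol > kkt_accept:
            raise ConvergenceError(
                f"graphical lasso did not converge at lambda={lam:g} "
                f"(KKT violation {viol:.3g})",
                n_iter=n_iter,
            )
    fit.loglik_basis, fit.objective = _objectives(S, prec, lam)
    return fit


def ebic_score(fit: PrecisionEstimate, n: int, p: int, gamma: float) -> float:
    """Extended BIC of a precision fit: −2ℓ(Θ̂) + E log n + 4γE log p.

    ℓ is the Gaussian log-likelihood at the fitted precision,
    (n/2)(log det Θ̂ − tr(Σ̂Θ̂)), dropping the additive constant
    −(np/2) log 2π which cancels across fits compared at the same (n, p).
    Using the likelihood itself (rather than the ℓ1-penalised objective)
    follows the standard eBIC convention for graphical-lasso paths; scoring
    the penalised objective instead double-counts the penalty and biases the
    criterion toward dense models.
    """
    if not 0 <= gamma <= 1:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if not np.isfinite(fit.loglik_basis):
        raise ValueError("fit carries no likelihood value; refit before scoring")
    loglik = 0.5 * n * fit.loglik_basis
    E = fit.n_edges
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def default_lambda_grid(
    S: np.ndarray, n_lambda: int = 30, min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced penalty grid from λmax (diagonal estimate) downward.

    λmax is the largest absolute off-diagonal covariance entry: at or above
    it every off-diagonal KKT bound is met and Θ̂ is diagonal.
    """
    off = S - np.diag(np.diag(S))
    lam_max = float(np.max(np.abs(off)))
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def select_lambda_ebic(
    x: ExpressionMatrix,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    standardize: bool = True,
    tol: float = 1e-4,
    max_iter: int = 200,
    n_lambda: int = 30,
    min_ratio: float = 0.01,
    patience: int | None = None,
) -> PrecisionEstimate:
    """Fit the graphical lasso over a penalty grid and keep the eBIC minimiser.

    Columns are standardised to unit variance by default so the penalty acts
    on the correlation scale (hub ranking then does not depend on abundance
    units).  The grid is scanned from sparse (large λ) to dense; ties in eBIC
    break toward the larger penalty (sparser model).  ``patience`` optionally
    stops the scan once eBIC has exceeded its running minimum that many
    consecutive times, skipping the densest (and slowest) fits.

    Raises
    ------
    ConvergenceError
        If every grid value fails to produce a converged fit.
    """
    if not 0 <= gamma <= 1:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    v = x.values
    if standardize:
        sd = v.std(axis=0)
        if np.any(sd == 0):
            bad = [x.feature_names[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance proteins cannot be standardized: {bad}")
        v = (v - v.mean(axis=0)) / sd
        x = ExpressionMatrix(v, x.feature_names, x.sample_ids)
    S = empirical_covariance(x)
    n, p = x.values.shape

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S, n_lambda=n_lambda, min_ratio=min_ratio)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")

    best: PrecisionEstimate | None = None
    edge_path: list[int] = []
    cov_init = None
    n_rising = 0
    for lam in lambda_grid:
        try:
            fit = graphical_lasso_fit(
                S, float(lam), tol=tol, max_iter=max_iter, cov_init=cov_init
            )
        except ConvergenceError as exc:
            if exc.fatal:
                # non-SPD at this density: every denser fit on the grid is
                # at least as hard (relevant when p > n), stop scanning
                break
            try:  # warm starts can cycle near the diagonal solution
                fit = graphical_lasso_fit(S, float(lam), tol=tol, max_iter=max_iter)
            except ConvergenceError as exc2:
                if exc2.fatal:
                    break
                continue
        cov_init = fit.covariance
        edge_path.append(fit.n_edges)
        fit.gamma = gamma
        fit.ebic_value = ebic_score(fit, n, p, gamma)
        if best is None or fit.ebic_value < best.ebic_value - 1e-12:
            best = fit
            n_rising = 0
        else:
            n_rising += 1
            if patience is not None and n_rising >= patience:
                break
    if best is None:
        raise ConvergenceError("graphical lasso failed at every grid value")
    _check_monotone_sparsity(edge_path, p)
    return best


def _check_monotone_sparsity(edge_path: list[int], p: int) -> None:
    """Edge counts along a descending-λ path should be non-decreasing.

    Small inversions can occur at finite solver tolerance; those are warned
    about, while gross violations indicate a broken path and raise.
    """
    arr = np.asarray(edge_path)
    if arr.size < 2:
        return
    drops = np.maximum(arr[:-1] - arr[1:], 0)
    worst = int(drops.max()) if drops.size else 0
    if worst == 0:
        return
    budget = max(2, int(0.05 * p * (p - 1) / 2))
    if worst > budget:
        raise AssertionError(
            f"edge count dropped by {worst} while relaxing the penalty; "
            "the graphical-lasso path is not trustworthy"
        )
    warnings.warn(
        f"minor non-monotonicity in the glasso edge path (max drop {worst})",
        RuntimeWarning,
        stacklevel=3,
    )


def partial_correlations(fit: PrecisionEstimate) -> np.ndarray:
    """Convert a precision matrix to partial correlations (sign reversal).

    ρ̂_jk = −θ̂_jk / √(θ̂_jj θ̂_kk) for j ≠ k, diagonal set to zero.
    """
    theta = fit.theta
    d = np.diag(theta)
    if np.any(d <= 0):
        raise InvalidPrecisionError(
            "precision matrix has nonpositive diagonal entries"
        )
    scale = np.sqrt(d)
    rho = -theta / np.outer(scale, scale)
    np.fill_diagonal(rho, 0.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return rho


def network_from_fit(
    fit: PrecisionEstimate, feature_names: list[str]
) -> PartialCorrelationNetwork:
    return PartialCorrelationNetwork(
        rho=partial_correlations(fit), feature_names=list(feature_names)
    )


def estimate_network(
    x: ExpressionMatrix, **select_kwargs
) -> tuple[PartialCorrelationNetwork, PrecisionEstimate]:
    """End-to-end GGM estimation: eBIC-tuned graphical lasso → ρ̂ network."""
    fit = select_lambda_ebic(x, **select_kwargs)
    return network_from_fit(fit, x.feature_names), fit


def kkt_violation(S: np.ndarray, fit: PrecisionEstimate) -> float:
    """Maximum stationarity violation of a graphical-lasso solution.

    At the optimum, W = Θ̂⁻¹ satisfies |S_jk − W_jk| ≤ λ where θ̂_jk = 0 and
    S_jk − W_jk = −λ sign(θ̂_jk) where θ̂_jk ≠ 0 (off-diagonal j ≠ k, with
    W_jj = S_jj + λ·0 on the diagonal).  Returns the largest absolute excess
    over the bound; ≈ 0 (within solver tolerance) for a converged fit.
    """
    lam = fit.lambda_used
    W = np.linalg.inv(fit.theta)
    R = S - W
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    zero = off & (np.abs(fit.theta) <= EDGE_TOL)
    nonzero = off & (np.abs(fit.theta) > EDGE_TOL)
    viol = 0.0
    if zero.any():
        viol = max(viol, float(np.max(np.abs(R[zero]) - lam)))
    if nonzero.any():
        viol = max(
            viol,
            float(np.max(np.abs(R[nonzero] + lam * np.sign(fit.theta[nonzero])))),
        )
    return viol
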