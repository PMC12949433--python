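"""Partially penalised adaptive-lasso regression.

The outcome model is Y = Uα + Nβ + ε, where U = (1, Z, H) collects the
intercept, clinical confounders and hub proteins (never penalised) and N
holds the non-hub proteins.  The estimator minimises

    L(α, β) = ‖Y − Uα − Nβ‖² + λ Σ_j w_j |β_j|,

with adaptive weights w_j = |β̃_j|^{−ν} built from a perturbed elastic-net
initial estimate β̃ (magnitudes floored at a small constant so weights stay
finite).  The pair (ν, λ) is chosen by k-fold cross-validation; the initial
estimator is recomputed inside each training fold so no outcome information
leaks from held-out samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from . import _solvers
from .errors import ConvergenceError
from .hubs import HubPartition
from .network import ExpressionMatrix

DEFAULT_NU_GRID = (0.5, 1.0, 2.0)
DEFAULT_N_LAMBDA = 50
DEFAULT_LAMBDA_MIN_RATIO = 1e-3


@dataclass
class DesignPartition:
    """Design split into the unpenalised block U = (1, Z, H) and non-hubs N.

    ``column_map`` lists, per coefficient position (U first, then N), the
    block label (intercept/confounder/hub/nonhub) and the original name.
    """

    u: np.ndarray
    n_mat: np.ndarray
    y: np.ndarray
    column_map: list[tuple[str, str]]

    def __post_init__(self):
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.n_mat = np.asarray(self.n_mat, dtype=float)
        if self.n_mat.ndim == 1:
            self.n_mat = self.n_mat.reshape(len(self.y), -1)
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.u.shape[0] != n or self.n_mat.shape[0] != n:
            raise ValueError("row counts of u, n_mat and y disagree")
        if self.t < 1:
            raise ValueError("unpenalised block must contain the intercept")
        if len(self.column_map) != self.t + self.q:
            raise ValueError("column_map does not cover every coefficient")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def t(self) -> int:
        return self.u.shape[1]

    @property
    def q(self) -> int:
        return self.n_mat.shape[1]

    def rows(self, idx: np.ndarray) -> "DesignPartition":
        return DesignPartition(
            u=self.u[idx], n_mat=self.n_mat[idx], y=self.y[idx],
            column_map=self.column_map,
        )


@dataclass
class NGFit:
    """A fitted network-guided model.

    ``alpha`` covers the unpenalised block (intercept, confounders, hubs) and
    ``beta`` the penalised non-hubs, both on the scale of the data the solver
    saw; ``objective_value`` is the attained value of the penalised least-
    squares objective on that scale.
    """

    alpha: np.ndarray
    beta: np.ndarray
    lambda_n: float
    nu: float
    weights: np.ndarray
    objective_value: float
    column_map: list[tuple[str, str]] = field(default_factory=list)
    n_iter: int = 0

    @property
    def selected_nonhubs(self) -> np.ndarray:
        """Positions j (within the non-hub block) with β̂_j ≠ 0 (Ĵn)."""
        return np.flatnonzero(self.beta != 0)


@dataclass
class CVChoice:
    nu_grid: list[float]
    lambda_path: dict[float, np.ndarray]
    k_folds: int
    cv_errors: dict[float, np.ndarray]
    chosen: tuple[float, float]


def build_partition(
    x: ExpressionMatrix,
    z: np.ndarray | None,
    y: np.ndarray,
    hubs: HubPartition,
    confounder_names: list[str] | None = None,
) -> DesignPartition:
    """Assemble U = [1 | Z | X_H] and N = X_N with a complete column map."""
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.values.shape
    if y.size != n:
        raise ValueError(f"outcome length {y.size} does not match {n} samples")
    if z is None or (hasattr(z, "shape") and np.asarray(z).size == 0):
        z = np.empty((n, 0))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] != n:
        raise ValueError(f"confounder rows {z.shape[0]} do not match {n} samples")
    c = z.shape[1]
    if confounder_names is None:
        confounder_names = [f"Z{k + 1}" for k in range(c)]
    if hubs.p != p:
        raise ValueError("hub partition does not match the expression matrix")
    bad = [i for i in hubs.hub_indices if not 0 <= i < p]
    if bad:
        raise ValueError(f"hub indices out of range: {bad}")

    u = np.column_stack([np.ones(n), z, x.values[:, hubs.hub_indices]])
    n_mat = x.values[:, hubs.nonhub_indices]
    column_map = (
        [("intercept", "(Intercept)")]
        + [("confounder", nm) for nm in confounder_names]
        + [("hub", x.feature_names[i]) for i in hubs.hub_indices]
        + [("nonhub", x.feature_names[i]) for i in hubs.nonhub_indices]
    )
    seen: set[str] = set()
    for _, nm in column_map[1:]:
        if nm in seen:
            raise RuntimeError(f"feature {nm!r} assigned to more than one block")
        seen.add(nm)
    return DesignPartition(u=u, n_mat=n_mat, y=y, column_map=column_map)


def _residualize(part: DesignPartition) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the unpenalised block out of y and N.

    Minimising over α for any fixed β gives exactly the penalised regression
    of M_U y on M_U N, with M_U the residual-maker of U, so the unpenalised
    block can be handled by residualisation without approximation.
    """
    P = np.linalg.pinv(part.u)
    beta_u_y = P @ part.y
    y_r = part.y - part.u @ beta_u_y
    n_r = part.n_mat - part.u @ (P @ part.n_mat)
    return y_r, n_r, P


def initial_estimator(
    part: DesignPartition,
    enet_mixing: float = 0.5,
    ridge_perturb: float | None = None,
    seed: int = 0,
    k_folds: int = 5,
) -> np.ndarray:
    """Perturbed elastic-net magnitudes |β̃_j| + perturbation for weighting.

    Fits an elastic net of y on the full design with U unpenalised (handled
    exactly by residualisation) and the penalty CV-tuned, then floors the
    absolute coefficients at ``ridge_perturb`` (default 1/n) so the adaptive
    weights |β̃|^{−ν} remain finite.
    """
    if not 0 < enet_mixing <= 1:
        raise ValueError(f"enet_mixing must lie in (0, 1], got {enet_mixing}")
    if ridge_perturb is None:
        ridge_perturb = 1.0 / part.n
    if part.q == 0:
        return np.empty(0)

    y_r, n_r, _ = _residualize(part)
    col_sd = n_r.std(axis=0)
    live = col_sd > 1e-12
    mags = np.zeros(part.q)
    if not live.any():
        warnings.warn(
            "all non-hub columns are degenerate after residualisation; "
            "initial magnitudes set to the perturbation floor",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(part.q, ridge_perturb)
    if not live.all():
        dead = [part.column_map[part.t + j][1] for j in np.flatnonzero(~live)]
        warnings.warn(
            f"zero-variance non-hub columns get the perturbation floor: {dead}",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.std(y_r) < 1e-12:
        # nothing left to explain; all magnitudes at the floor
        return np.full(part.q, ridge_perturb)

    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet = ElasticNetCV(
            l1_ratio=enet_mixing,
            cv=cv,
            fit_intercept=False,
            alphas=40,
            max_iter=5000,
        )
        enet.fit(n_r[:, live], y_r)
    mags[live] = np.abs(enet.coef_)
    return mags + ridge_perturb


def adaptive_weights(beta_tilde_mag: np.ndarray, nu: float) -> np.ndarray:
    """w_j = |β̃_j|^{−ν}: larger initial magnitudes get lighter penalties."""
    mag = np.asarray(beta_tilde_mag, dtype=float)
    if nu <= 0:
        raise ValueError(f"nu must be positive, got {nu}")
    if np.any(mag <= 0):
        raise ValueError("initial magnitudes must be strictly positive")
    return mag ** (-nu)


def _pinv_u(u: np.ndarray) -> np.ndarray:
    t = u.shape[1]
    if np.linalg.matrix_rank(u) < t:
        warnings.warn(
            "unpenalised block is rank deficient; fitting via pseudoinverse",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.linalg.pinv(u)


def fit_ng(
    part: DesignPartition,
    lam: float,
    weights: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> NGFit:
    """Minimise ‖y − Uα − Nβ‖² + λ Σ w_j|β_j| by block coordinate descent.

    The data are used exactly as given (no internal rescaling); the exact
    least-squares α-update and per-coordinate soft-thresholding are iterated
    until the relative objective change drops below ``tol``.

    Raises
    ------
    ConvergenceError
        If the sweep budget is exhausted before the tolerance is met.
    """
    if lam < 0:
        raise ValueError(f"penalty must be nonnegative, got {lam}")
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != part.q:
        raise ValueError(f"expected {part.q} weights, got {weights.size}")
    if np.any(weights < 0):
        raise ValueError("penalty weights must be nonnegative")

    P = _pinv_u(part.u)
    alphas, betas, n_iters, objs, mono, conv = _solvers.cd_path(
        np.ascontiguousarray(part.u),
        np.ascontiguousarray(P),
        np.ascontiguousarray(part.n_mat),
        np.ascontiguousarray(part.y),
        weights,
        np.array([float(lam)]),
        tol,
        max_iter,
    )
    if not mono[0]:
        raise AssertionError(
            "objective increased during block coordinate descent"
        )
    if not conv[0]:
        raise ConvergenceError(
            f"partially penalised fit did not converge in {max_iter} sweeps",
            n_iter=int(n_iters[0]),
            trace=[float(objs[0])],
        )
    return NGFit(
        alpha=alphas[0],
        beta=betas[0],
        lambda_n=float(lam),
        nu=float("nan"),
        weights=weights,
        objective_value=float(objs[0]),
        column_map=list(part.column_map),
        n_iter=int(n_iters[0]),
    )


def predict(fit: NGFit, u_new: np.ndarray, n_new: np.ndarray) -> np.ndarray:
    """Linear predictions u_new·α̂ + n_new·β̂."""
    u_new = np.atleast_2d(np.asarray(u_new, dtype=float))
    n_new = np.asarray(n_new, dtype=float)
    if n_new.ndim == 1:
        n_new = n_new.reshape(u_new.shape[0], -1)
    if u_new.shape[1] != fit.alpha.size:
        raise ValueError(
            f"u_new has {u_new.shape[1]} columns, expected {fit.alpha.size}"
        )
    if n_new.shape[1] != fit.beta.size:
        raise ValueError(
            f"n_new has {n_new.shape[1]} columns, expected {fit.beta.size}"
        )
    return u_new @ fit.alpha + n_new @ fit.beta


def lambda_max(part_std: DesignPartition, weights: np.ndarray) -> float:
    """Smallest penalty that zeroes every penalised coefficient.

    From the KKT conditions at β = 0: λmax = max_j 2|N_jᵀ M_U y| / w_j.
    """
    y_r, n_r, _ = _residualize(part_std)
    grad = 2.0 * np.abs(n_r.T @ y_r)
    w = np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore"):
        vals = np.where(w > 0, grad / w, np.inf)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return 1.0
    return float(finite.max())


def _standardize_nonhubs(
    part: DesignPartition,
) -> tuple[DesignPartition, np.ndarray, np.ndarray]:
    """Scale non-hub columns to unit variance (penalty comparability)."""
    mu = part.n_mat.mean(axis=0)
    sd = part.n_mat.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    n_std = (part.n_mat - mu) / sd_safe
    return (
        DesignPartition(
            u=part.u, n_mat=n_std, y=part.y, column_map=part.column_map
        ),
        mu,
        sd_safe,
    )


def _fit_path(part, weights, lam_path, tol, max_iter):
    P = _pinv_u(part.u)
    alphas, betas, n_iters, objs, mono, conv = _solvers.cd_path(
        np.ascontiguousarray(part.u),
        np.ascontiguousarray(P),
        np.ascontiguousarray(part.n_mat),
        np.ascontiguousarray(part.y),
        np.asarray(weights, dtype=float),
        np.asarray(lam_path, dtype=float),
        tol,
        max_iter,
    )
    if not mono.all():
        raise AssertionError("objective increased during a path fit")
    return alphas, betas, conv


def cv_select(
    part: DesignPartition,
    nu_grid=DEFAULT_NU_GRID,
    k_folds: int = 5,
    seed: int = 0,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    enet_mixing: float = 0.5,
    ridge_perturb: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[CVChoice, NGFit]:
    """Choose (ν, λ) by k-fold CV and refit on the full data.

    Non-hub columns are standardised internally for the coordinate updates;
    the returned fit reports coefficients on the original scale.  The λ path
    per ν runs over ``n_lambda`` log-spaced values from the smallest penalty
    that zeroes all of β down to ``lambda_min_ratio`` of it.  Fold assignment
    is seed-deterministic, the initial estimator is recomputed inside each
    training fold, ties in CV error break toward the larger λ then larger ν.
    """
    if k_folds not in (5, 10):
        raise ValueError(f"k_folds must be 5 or 10, got {k_folds}")
    if part.n < 2 * k_folds:
        raise ValueError("need at least 2 samples per fold")
    nu_grid = [float(v) for v in nu_grid]

    part_std, mu_n, sd_n = _standardize_nonhubs(part)

    if part.q == 0:
        # no penalised block: plain least squares on U
        fit = fit_ng(part, 0.0, np.empty(0), tol=tol, max_iter=max_iter)
        fit.nu = nu_grid[0]
        choice = CVChoice(
            nu_grid=nu_grid, lambda_path={}, k_folds=k_folds,
            cv_errors={}, chosen=(nu_grid[0], 0.0),
        )
        return choice, fit

    mags_full = initial_estimator(
        part_std, enet_mixing=enet_mixing, ridge_perturb=ridge_perturb, seed=seed
    )
    # one grid of shrinkage fractions shared by all folds: fold fits run at
    # ratio * lambda_max(fold), so a grid index means the same relative
    # penalty everywhere even though adaptive weights differ per fold
    ratios = np.geomspace(1.0, lambda_min_ratio, n_lambda)
    paths: dict[float, np.ndarray] = {}
    for nu in nu_grid:
        w_full = adaptive_weights(mags_full, nu)
        paths[nu] = lambda_max(part_std, w_full) * ratios

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    sq_err = {nu: np.zeros(n_lambda) for nu in nu_grid}
    n_val_total = 0
    for fold_id, (tr, va) in enumerate(kf.split(part.y)):
        if np.std(part.y[tr]) < 1e-12:
            warnings.warn(
                f"fold {fold_id} has constant outcome; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        tr_part = part.rows(tr)
        tr_std, mu_tr, sd_tr = _standardize_nonhubs(tr_part)
        mags_tr = initial_estimator(
            tr_std, enet_mixing=enet_mixing, ridge_perturb=ridge_perturb,
            seed=seed + 1000 + fold_id,
        )
        u_va = part.u[va]
        n_va = (part.n_mat[va] - mu_tr) / sd_tr
        for nu in nu_grid:
            w_tr = adaptive_weights(mags_tr, nu)
            fold_path = lambda_max(tr_std, w_tr) * ratios
            alphas, betas, _ = _fit_path(tr_std, w_tr, fold_path, tol, max_iter)
            pred = u_va @ alphas.T + n_va @ betas.T  # (n_va, L)
            sq_err[nu] += ((part.y[va][:, None] - pred) ** 2).sum(axis=0)
        n_val_total += va.size
    if n_val_total == 0:
        raise ValueError("every CV fold was degenerate")
    cv_errors = {nu: sq_err[nu] / n_val_total for nu in nu_grid}

    # minimise mean CV error; ties -> larger lambda, then larger nu
    best = None
    for nu in nu_grid:
        for lam_idx, lam in enumerate(paths[nu]):
            err = cv_errors[nu][lam_idx]
            key = (err, -lam, -nu)
            if best is None or key < best[0]:
                best = (key, nu, float(lam))
    _, nu_star, lam_star = best

    w_star = adaptive_weights(mags_full, nu_star)
    # warm-started descent down the path to the chosen penalty
    path_star = paths[nu_star]
    upto = np.searchsorted(-path_star, -lam_star) + 1
    alphas, betas, conv = _fit_path(part_std, w_star, path_star[:upto], tol, max_iter)
    if not conv[-1]:
        raise ConvergenceError(
            f"final refit did not converge in {max_iter} sweeps"
        )
    alpha_std, beta_std = alphas[-1], betas[-1]

    # map back to the original non-hub scale
    beta = beta_std / sd_n
    alpha = alpha_std.copy()
    alpha[0] -= float(mu_n @ beta)
    pen = float(np.sum(w_star * np.abs(beta_std)))
    resid = part.y - part.u @ alpha - part.n_mat @ beta
    fit = NGFit(
        alpha=alpha,
        beta=beta,
        lambda_n=lam_star,
        nu=nu_star,
        weights=w_star,
        objective_value=float(resid @ resid + lam_star * pen),
        column_map=list(part.column_map),
    )
    choice = CVChoice(
        nu_grid=nu_grid, lambda_path=paths, k_folds=k_folds,
        cv_errors=cv_errors, chosen=(nu_star, lam_star),
    )
    return choice, fit
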