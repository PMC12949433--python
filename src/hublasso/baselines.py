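"""Reference penalised regressions the network-guided method is benchmarked
against.

All four baselines treat proteins uniformly — none of them exempts hub
proteins from the penalty.  The adaptive lasso is the direct ablation of the
network-guided fit: identical machinery (perturbed-elastic-net weights, ν
grid, 5-fold CV over (ν, λ)) with an empty hub set, keeping the intercept
and clinical confounders unpenalised as adjustment covariates.  Lasso,
elastic net (mixing 0.5) and ridge are run the standard way (intercept free,
one uniform penalty over confounders and proteins) with 5-fold CV over λ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .hubs import HubPartition
from .network import ExpressionMatrix
from .regression import build_partition, cv_select

BASELINE_METHODS = ("alasso", "lasso", "enet", "ridge")


@dataclass
class BaselineFit:
    """Coefficients over (intercept, confounders, proteins) for one baseline."""

    method: str
    coefficients: np.ndarray  # length 1 + c + p
    lam: float
    extra: dict

    def predict(self, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        design = np.column_stack([np.ones(z.shape[0]), z, x])
        if design.shape[1] != self.coefficients.size:
            raise ValueError("design width does not match coefficient vector")
        return design @ self.coefficients

    @property
    def candidate_coefficients(self) -> np.ndarray:
        """Confounder and protein coefficients (intercept excluded)."""
        return self.coefficients[1:]


def _standardized(design: np.ndarray):
    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    return (design - mu) / sd_safe, mu, sd_safe


def fit_baseline(
    method: str,
    x: ExpressionMatrix,
    z: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    enet_mixing: float = 0.5,
) -> BaselineFit:
    """Fit one uniformly penalised baseline with CV-chosen tuning."""
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; use one of {BASELINE_METHODS}")
    y = np.asarray(y, dtype=float).ravel()
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, p = x.values.shape
    c = z.shape[1]

    if method == "alasso":
        # the h = 0 ablation of the network-guided fit: every protein is
        # penalised, the confounders stay in the unpenalised block
        part = build_partition(
            x,
            z,
            y,
            HubPartition(
                hub_indices=[], nonhub_indices=list(range(p)), h=0,
                delta=float("nan"), tau=-1,
            ),
        )
        choice, fit = cv_select(part, k_folds=k_folds, seed=seed,
                                enet_mixing=enet_mixing)
        coefs = np.concatenate([fit.alpha, fit.beta])  # intercept, then Z, X
        nu, lam = choice.chosen
        return BaselineFit(
            method="alasso", coefficients=coefs, lam=lam, extra={"nu": nu}
        )

    design = np.column_stack([z, x.values])
    design_std, mu, sd = _standardized(design)
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "lasso":
            model = LassoCV(cv=cv, alphas=100, max_iter=10000)
            model.fit(design_std, y)
            lam, extra = float(model.alpha_), {}
        elif method == "enet":
            model = ElasticNetCV(
                l1_ratio=enet_mixing, cv=cv, alphas=100, max_iter=10000
            )
            model.fit(design_std, y)
            lam, extra = float(model.alpha_), {"mixing": enet_mixing}
        else:  # ridge
            alphas = np.geomspace(1e-4, 1e4, 100)
            model = RidgeCV(alphas=alphas, cv=cv)
            model.fit(design_std, y)
            lam, extra = float(model.alpha_), {}
    coef_std = np.asarray(model.coef_, dtype=float)
    coef = coef_std / sd
    intercept = float(model.intercept_) - float(mu @ coef)
    return BaselineFit(
        method=method,
        coefficients=np.concatenate([[intercept], coef]),
        lam=lam,
        extra=extra,
    )
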