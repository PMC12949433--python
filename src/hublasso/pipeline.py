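"""End-to-end network-guided fit: GGM network → hubs → partial penalisation.

The two stages are run in sequence on the training data: hub identification
happens once, before cross-validation of the regression stage, so the hub set
is fixed across CV folds (the network stage never sees the outcome, only the
protein matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hubs import CentralityScores, HubPartition, identify_hubs
from .network import (
    ExpressionMatrix,
    PartialCorrelationNetwork,
    PrecisionEstimate,
    estimate_network,
)
from .regression import CVChoice, NGFit, build_partition, cv_select, predict


@dataclass
class NetworkGuidedResult:
    """Everything produced by one network-guided run."""

    network: PartialCorrelationNetwork
    precision: PrecisionEstimate
    centrality: CentralityScores
    hubs: HubPartition
    cv: CVChoice
    fit: NGFit
    feature_names: list[str] = field(default_factory=list)
    confounder_names: list[str] = field(default_factory=list)

    def predict(self, x_new: np.ndarray, z_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        z_new = np.atleast_2d(np.asarray(z_new, dtype=float))
        u_new = np.column_stack(
            [np.ones(x_new.shape[0]), z_new, x_new[:, self.hubs.hub_indices]]
        )
        n_new = x_new[:, self.hubs.nonhub_indices]
        return predict(self.fit, u_new, n_new)

    @property
    def candidate_coefficients(self) -> np.ndarray:
        """Coefficients over (confounders, proteins) in original column order.

        Hub coefficients come from the unpenalised block, non-hub ones from
        the penalised block; the intercept is excluded.  Used for selection
        metrics, where any exactly nonzero entry counts as selected.
        """
        c = len(self.confounder_names)
        p = len(self.feature_names)
        out = np.zeros(c + p)
        out[:c] = self.fit.alpha[1 : 1 + c]
        for pos, j in enumerate(self.hubs.hub_indices):
            out[c + j] = self.fit.alpha[1 + c + pos]
        for pos, j in enumerate(self.hubs.nonhub_indices):
            out[c + j] = self.fit.beta[pos]
        return out

    def coefficient_table(self) -> pd.DataFrame:
        blocks, names = zip(*self.fit.column_map)
        estimates = np.concatenate([self.fit.alpha, self.fit.beta])
        selected = [
            1 if (b in ("intercept", "confounder", "hub") or est != 0) else 0
            for b, est in zip(blocks, estimates)
        ]
        return pd.DataFrame(
            {
                "feature": names,
                "block": blocks,
                "estimate": estimates,
                "selected": selected,
            }
        )


def fit_network_guided(
    x: ExpressionMatrix,
    z: np.ndarray,
    y: np.ndarray,
    delta: float,
    tau: int | None = None,
    centrality_measure: str = "degree",
    gamma: float = 0.5,
    n_lambda_net: int = 30,
    lambda_min_ratio_net: float = 0.01,
    net_tol: float = 1e-4,
    net_max_iter: int = 200,
    net_patience: int | None = None,
    standardize_net: bool = True,
    nu_grid=(0.5, 1.0, 2.0),
    k_folds: int = 5,
    seed: int = 0,
    confounder_names: list[str] | None = None,
) -> NetworkGuidedResult:
    """Run the full network-guided pipeline on one training set.

    ``delta`` (hub proportion) and ``tau`` (hub cap, default ⌊(p+20)/16⌋)
    control the hub count; ``gamma`` is the eBIC sparsity hyperparameter.
    With h = 0 (tiny ``delta``) the fit degrades gracefully to a plain
    adaptive lasso with unpenalised confounders.
    """
    net, prec = estimate_network(
        x,
        gamma=gamma,
        n_lambda=n_lambda_net,
        min_ratio=lambda_min_ratio_net,
        tol=net_tol,
        max_iter=net_max_iter,
        patience=net_patience,
        standardize=standardize_net,
    )
    scores, hub_part = identify_hubs(
        net, delta=delta, tau_override=tau, measure=centrality_measure
    )
    part = build_partition(x, z, y, hub_part, confounder_names=confounder_names)
    choice, fit = cv_select(part, nu_grid=nu_grid, k_folds=k_folds, seed=seed)
    c = 0 if z is None else np.atleast_2d(np.asarray(z)).shape[1]
    return NetworkGuidedResult(
        network=net,
        precision=prec,
        centrality=scores,
        hubs=hub_part,
        cv=choice,
        fit=fit,
        feature_names=list(x.feature_names),
        confounder_names=(
            confounder_names
            if confounder_names is not None
            else [f"Z{k + 1}" for k in range(c)]
        ),
    )
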