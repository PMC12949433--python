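"""Hub-protein identification from a partial-correlation network.

Hubs are the nodes that hold a co-expression network together.  The default
score is weighted degree centrality, ϕ̂_k = Σ_j |ρ̂_jk|: the marginal sum of
the absolute partial-correlation (association) matrix.  The number of hubs is
capped by the rule

    h = min(⌊pδ⌋, τ),      τ = ⌊(p + 20) / 16⌋  by default,

so that the unpenalised block of the downstream regression stays moderate.
Betweenness and eigenvector centrality are available as alternatives for
sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import PartialCorrelationNetwork

VALID_MEASURES = ("degree", "betweenness", "eigenvector")


@dataclass
class CentralityScores:
    scores: np.ndarray
    measure: str
    feature_names: list[str]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.measure not in VALID_MEASURES:
            raise ValueError(f"unknown centrality measure {self.measure!r}")
        if len(self.feature_names) != self.scores.size:
            raise ValueError("feature_names length does not match scores")
        if np.any(self.scores < -1e-12):
            raise ValueError("centrality scores must be nonnegative")

    def table(self) -> pd.DataFrame:
        order = ranked_order(self.scores)
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.scores.size + 1),
                "feature": [self.feature_names[i] for i in order],
                "centrality": self.scores[order],
            }
        )


@dataclass
class HubPartition:
    """Disjoint split of feature positions into hubs H and non-hubs N."""

    hub_indices: list[int]
    nonhub_indices: list[int]
    h: int
    delta: float
    tau: int

    def __post_init__(self):
        if len(self.hub_indices) != self.h:
            raise ValueError("hub set size does not match h")
        if set(self.hub_indices) & set(self.nonhub_indices):
            raise ValueError("hub and non-hub sets overlap")

    @property
    def p(self) -> int:
        return len(self.hub_indices) + len(self.nonhub_indices)

    @property
    def q(self) -> int:
        return len(self.nonhub_indices)


def degree_centrality(net: PartialCorrelationNetwork) -> CentralityScores:
    """ϕ̂_k = Σ_{j≠k} |ρ̂_jk| (diagonal already zero by convention)."""
    scores = np.abs(net.rho).sum(axis=0)
    return CentralityScores(
        scores=scores, measure="degree", feature_names=list(net.feature_names)
    )


def alt_centrality(
    net: PartialCorrelationNetwork, measure: str
) -> CentralityScores:
    """Betweenness or eigenvector centrality on the weighted network.

    Betweenness uses edge distance 1/|ρ̂_jk| over nonzero edges, so stronger
    partial correlations mean shorter paths; disconnected graphs are handled
    per component.  Eigenvector centrality is the principal eigenvector of
    |ρ̂|, normalised to maximum 1 (Perron–Frobenius convention).
    """
    if measure not in ("betweenness", "eigenvector"):
        raise ValueError(f"unknown centrality measure {measure!r}")
    a = np.abs(net.rho)
    p = a.shape[0]
    if not a.any():
        warnings.warn(
            "network has no edges; centrality scores are degenerate (uniform)",
            RuntimeWarning,
            stacklevel=2,
        )
        return CentralityScores(
            scores=np.zeros(p), measure=measure,
            feature_names=list(net.feature_names),
        )
    if measure == "betweenness":
        g = nx.Graph()
        g.add_nodes_from(range(p))
        iu, ju = np.triu_indices(p, k=1)
        mask = a[iu, ju] > 0
        g.add_weighted_edges_from(
            zip(iu[mask].tolist(), ju[mask].tolist(), (1.0 / a[iu, ju][mask])),
            weight="distance",
        )
        bc = nx.betweenness_centrality(g, weight="distance", normalized=True)
        scores = np.array([bc[k] for k in range(p)])
    else:
        eigvals, eigvecs = np.linalg.eigh(a)
        v = eigvecs[:, -1]
        v = np.abs(v)  # Perron vector of a nonnegative matrix
        scores = v / v.max()
    return CentralityScores(
        scores=scores, measure=measure, feature_names=list(net.feature_names)
    )


def centrality(net: PartialCorrelationNetwork, measure: str = "degree"):
    if measure == "degree":
        return degree_centrality(net)
    return alt_centrality(net, measure)


def default_tau(p: int) -> int:
    """τ = ⌊(p + 20)/16⌋: keeps the unpenalised block moderate."""
    return (p + 20) // 16


def hub_count(p: int, delta: float, tau_override: int | None = None) -> int:
    """Number of hubs h = min(⌊pδ⌋, τ)."""
    if p < 1:
        raise ValueError("p must be positive")
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    tau = default_tau(p) if tau_override is None else int(tau_override)
    return min(math.floor(p * delta), tau)


def ranked_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; ties broken by ascending index."""
    return np.argsort(-np.asarray(scores), kind="stable")


def select_hubs(scores: CentralityScores, h: int,
                delta: float = float("nan"), tau: int = -1) -> HubPartition:
    """Partition features into the top-h hubs and the remaining non-hubs."""
    p = scores.scores.size
    if not 0 <= h <= p:
        raise ValueError(f"h must lie in [0, {p}], got {h}")
    order = ranked_order(scores.scores)
    hub = sorted(order[:h].tolist())
    nonhub = sorted(order[h:].tolist())
    return HubPartition(
        hub_indices=hub, nonhub_indices=nonhub, h=h, delta=delta, tau=tau
    )


def identify_hubs(
    net: PartialCorrelationNetwork,
    delta: float,
    tau_override: int | None = None,
    measure: str = "degree",
) -> tuple[CentralityScores, HubPartition]:
    """Score nodes and apply the h = min(⌊pδ⌋, τ) rule in one step."""
    scores = centrality(net, measure)
    p = net.n_features
    tau = default_tau(p) if tau_override is None else int(tau_override)
    h = hub_count(p, delta, tau_override)
    return scores, select_hubs(scores, h, delta=delta, tau=tau)


def hub_table(scores: CentralityScores, part: HubPartition) -> pd.DataFrame:
    """Ranked centrality table with hub flags, ready for export."""
    order = ranked_order(scores.scores)
    hubs = set(part.hub_indices)
    return pd.DataFrame(
        {
            "rank": np.arange(1, scores.scores.size + 1),
            "feature": [scores.feature_names[i] for i in order],
            "centrality": scores.scores[order],
            "is_hub": [int(i in hubs) for i in order],
        }
    )
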