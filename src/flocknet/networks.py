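"""Simple-ratio-index networks and node-level centrality metrics.

The gambit of the group turns each grouping event into a clique of
pairwise associations; the simple ratio index (SRI) then weights a dyad
by x / (x + y), where x counts groups containing both individuals and y
counts groups containing exactly one of them. The result is a weighted,
undirected network with weights in [0, 1] and no self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SocialNetwork",
    "NetworkSummary",
    "build_sri_network",
    "prune_isolates",
    "network_summary",
    "node_degree_strength",
    "node_betweenness",
    "node_metrics",
]


@dataclass
class SocialNetwork:
    """Weighted undirected network over an ordered node set.

    ``weights`` is a symmetric (n, n) matrix with zero diagonal and
    entries in [0, 1]; a zero entry means no edge.
    """

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if n and not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if n and (w.min() < 0 or w.max() > 1.0 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> set[frozenset]:
        """Unordered dyads with strictly positive weight."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return {frozenset((self.nodes[a], self.nodes[b])) for a, b in zip(i, j)}

    def to_networkx(self, cost_transform: str | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        i, j = np.nonzero(np.triu(self.weights, k=1))
        for a, b in zip(i, j):
            w = float(self.weights[a, b])
            attrs = {"weight": w}
            if cost_transform == "reciprocal":
                attrs["cost"] = 1.0 / w
            g.add_edge(self.nodes[a], self.nodes[b], **attrs)
        return g

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame({
            "i": [self.nodes[a] for a in i],
            "j": [self.nodes[b] for b in j],
            "weight": self.weights[i, j],
        })

    def write_edge_list(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_edge_list().to_csv(path, index=False)
        return path

    def write_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        nx.write_graphml(self.to_networkx(), path)
        return path

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, nodes=None) -> "SocialNetwork":
        if nodes is None:
            nodes = sorted(set(df["i"]) | set(df["j"]))
        idx = {v: k for k, v in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for _, row in df.iterrows():
            a, b = idx[row["i"]], idx[row["j"]]
            w[a, b] = w[b, a] = row["weight"]
        return cls(nodes=list(nodes), weights=w)


@dataclass
class NetworkSummary:
    V: int
    E: int
    D: float


def build_sri_network(gbi) -> SocialNetwork:
    """Scale a group-by-individual matrix into SRI edge weights.

    weight(a, b) = x / (x + y) with x = #groups containing both and
    y = #groups containing exactly one; dyads that never co-occur get
    weight 0 (no edge), not NaN.
    """
    x_mat = gbi.incidence.astype(float)
    if x_mat.size == 0:
        return SocialNetwork(nodes=list(gbi.individuals),
                             weights=np.zeros((len(gbi.individuals),) * 2))
    both = x_mat.T @ x_mat                      # x: joint occurrences
    occ = x_mat.sum(axis=0)                     # per-individual group counts
    denom = occ[:, None] + occ[None, :] - both  # x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, both / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return SocialNetwork(nodes=list(gbi.individuals), weights=w)


def prune_isolates(net: SocialNetwork) -> SocialNetwork:
    """Drop degree-0 individuals; idempotent."""
    keep = np.flatnonzero((net.weights > 0).sum(axis=1) > 0)
    return SocialNetwork(nodes=[net.nodes[i] for i in keep],
                         weights=net.weights[np.ix_(keep, keep)])


def network_summary(net: SocialNetwork) -> NetworkSummary:
    v = net.n_nodes
    e = int((np.triu(net.weights, k=1) > 0).sum())
    max_e = v * (v - 1) / 2
    return NetworkSummary(V=v, E=e, D=e / max_e if max_e else 0.0)


def node_degree_strength(net: SocialNetwork) -> pd.DataFrame:
    """Degree (count of associates) and strength (summed edge weights)."""
    return pd.DataFrame({
        "individual": net.nodes,
        "degree": (net.weights > 0).sum(axis=1).astype(int),
        "strength": net.weights.sum(axis=1),
    })


def node_betweenness(net: SocialNetwork,
                     cost_transform: str = "reciprocal") -> pd.DataFrame:
    """Weighted betweenness: geodesic counts on reciprocal-weight costs.

    Strong edges are short: the cost of an edge is 1/weight. Counts are
    unnormalized, endpoints excluded, and equal-cost geodesics are split
    fractionally — the convention of standard graph libraries.
    """
    if cost_transform != "reciprocal":
        raise ValueError("only the reciprocal cost transform is supported")
    g = net.to_networkx(cost_transform="reciprocal")
    bc = nx.betweenness_centrality(g, weight="cost", normalized=False)
    return pd.DataFrame({
        "individual": net.nodes,
        "betweenness": [bc[v] for v in net.nodes],
    })


def node_metrics(net: SocialNetwork) -> pd.DataFrame:
    """Degree, strength and weighted betweenness in one table."""
    out = node_degree_strength(net)
    out["betweenness"] = node_betweenness(net)["betweenness"].to_numpy()
    return out
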