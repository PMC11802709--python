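"""Pairwise network similarity with permutation-based significance.

Networks built from the same detection stream under different
association definitions are compared on four axes: shared dyads
(Jaccard over edge sets), shared clusters (Jaccard over closed
triangles), edge-weight predictability (MRQAP: regression of one scaled
adjacency matrix on the other with node-label permutation significance)
and matrix correlation (Mantel test, Pearson, node permutations).

Significance against chance grouping uses the pre-network permutation
null: each individual's column of the group-by-individual matrix is
shuffled across groups without replacement, preserving how often each
bird was detected while randomising who it was detected with; the
networks and the similarity statistic are then rebuilt per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .associations import GroupByIndividualMatrix
from .networks import SocialNetwork, build_sri_network

__all__ = [
    "ComparisonResult",
    "NullDistribution",
    "align_networks",
    "jaccard_edges",
    "jaccard_triangles",
    "mrqap_simple",
    "mantel",
    "permute_gbi",
    "permutation_null",
    "compare_networks",
]


@dataclass
class ComparisonResult:
    jaccard_edges: float
    jaccard_triangles: float
    mrqap_coef: float
    mrqap_p: float
    mantel_r: float
    mantel_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NullDistribution:
    statistic: str
    observed: float
    null_values: np.ndarray
    empirical_p: float


def align_networks(a: SocialNetwork, b: SocialNetwork
                   ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Embed both weight matrices on the union node set (missing dyads 0)."""
    nodes = sorted(set(a.nodes) | set(b.nodes))
    idx = {v: k for k, v in enumerate(nodes)}
    out = []
    for net in (a, b):
        w = np.zeros((len(nodes), len(nodes)))
        pos = [idx[v] for v in net.nodes]
        w[np.ix_(pos, pos)] = net.weights
        out.append(w)
    return nodes, out[0], out[1]


def jaccard_edges(a: SocialNetwork, b: SocialNetwork) -> float:
    """|E_a ∩ E_b| / |E_a ∪ E_b| over positive-weight dyads; both empty → 1."""
    ea, eb = a.edge_set(), b.edge_set()
    union = ea | eb
    if not union:
        return 1.0
    return len(ea & eb) / len(union)


def _triangle_set(net: SocialNetwork) -> set[frozenset]:
    adj = net.weights > 0
    tri: set[frozenset] = set()
    n = net.n_nodes
    for i in range(n):
        nbr = np.flatnonzero(adj[i])
        nbr = nbr[nbr > i]
        for a, b in combinations(nbr, 2):
            if adj[a, b]:
                tri.add(frozenset((net.nodes[i], net.nodes[a], net.nodes[b])))
    return tri


def jaccard_triangles(a: SocialNetwork, b: SocialNetwork) -> float:
    """Jaccard over the node-triples forming closed triangles."""
    ta, tb = _triangle_set(a), _triangle_set(b)
    union = ta | tb
    if not union:
        return 1.0
    return len(ta & tb) / len(union)


def _offdiag(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return w[mask]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance matrix: slope undefined")
    return (v - v.mean()) / sd


def _permute_matrix(w: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return w[np.ix_(perm, perm)]


def mrqap_simple(a: SocialNetwork, b: SocialNetwork,
                 n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Simple MRQAP: slope of b's scaled adjacency on a's, QAP p-value.

    Off-diagonal entries of both matrices are standardized, the OLS
    slope is the effect size, and significance comes from jointly
    permuting the rows and columns (node labels) of the predictor
    matrix; two-sided extremity, (1 + k) / (1 + n_perm).
    """
    _, wa, wb = align_networks(a, b)
    y = _standardize(_offdiag(wb))
    x = _standardize(_offdiag(wa))
    coef = float(x @ y / (x @ x))
    rng = np.random.default_rng(seed)
    n = wa.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = _standardize(_offdiag(_permute_matrix(wa, perm)))
        if abs(float(xp @ y / (xp @ xp))) >= abs(coef) - 1e-12:
            count += 1
    return coef, (1 + count) / (1 + n_perm)


def mantel(a: SocialNetwork, b: SocialNetwork,
           n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson correlation of off-diagonal weight vectors.

    p is the one-sided (greater) proportion of node-permuted
    correlations at least as large as the observed, with the
    (1 + k) / (1 + n_perm) correction.
    """
    _, wa, wb = align_networks(a, b)
    x, y = _offdiag(wa), _offdiag(wb)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance matrix: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = wa.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = np.corrcoef(_offdiag(_permute_matrix(wa, perm)), y)[0, 1]
        if rp >= r - 1e-12:
            count += 1
    return r, (1 + count) / (1 + n_perm)


def mantel_exhaustive(a: SocialNetwork, b: SocialNetwork) -> tuple[float, float]:
    """Exact Mantel p by full enumeration of node permutations (tiny n only)."""
    _, wa, wb = align_networks(a, b)
    y = _offdiag(wb)
    r = float(np.corrcoef(_offdiag(wa), y)[0, 1])
    n = wa.shape[0]
    if n > 7:
        raise ValueError("exhaustive enumeration limited to n <= 7")
    count, total = 0, 0
    for perm in permutations(range(n)):
        rp = np.corrcoef(_offdiag(_permute_matrix(wa, np.array(perm))), y)[0, 1]
        total += 1
        if rp >= r - 1e-12:
            count += 1
    return r, count / total


def permute_gbi(gbi: GroupByIndividualMatrix,
                rng: np.random.Generator | int = 0) -> GroupByIndividualMatrix:
    """Shuffle each individual's occurrence column without replacement.

    Column sums (how often each bird was seen in a group) are preserved
    exactly; row sums (group sizes) generally are not. Group metadata is
    dropped — a permuted GBI is a statistical object, not an event log.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    inc = gbi.incidence.copy()
    for c in range(inc.shape[1]):
        inc[:, c] = rng.permutation(inc[:, c])
    return GroupByIndividualMatrix(individuals=list(gbi.individuals),
                                   incidence=inc, groups=None)


def _safe(fn):
    # degenerate permuted networks (no edges -> zero variance) count as
    # zero similarity rather than aborting a null distribution
    def wrapped(a, b):
        try:
            return fn(a, b)
        except ValueError:
            return 0.0
    return wrapped


_STATISTICS = {
    "jaccard_edges": lambda a, b: jaccard_edges(a, b),
    "jaccard_triangles": lambda a, b: jaccard_triangles(a, b),
    "mrqap_coef": _safe(lambda a, b: mrqap_simple(a, b, n_perm=0)[0]),
    "mantel_r": _safe(lambda a, b: mantel(a, b, n_perm=0)[0]),
}


def permutation_null(gbi_a: GroupByIndividualMatrix,
                     gbi_b: GroupByIndividualMatrix,
                     statistic: str = "mantel_r",
                     n_perm: int = 1000, seed: int = 0) -> NullDistribution:
    """Pre-network permutation null for a named similarity statistic.

    Per replicate both GBIs are independently column-shuffled, both SRI
    networks rebuilt, and the statistic recomputed. The empirical p is
    (1 + #{null ≥ observed}) / (1 + n_perm) — one-sided, since every
    statistic here grows with similarity.
    """
    if statistic not in _STATISTICS:
        raise KeyError(f"unknown statistic {statistic!r}; "
                       f"choose from {sorted(_STATISTICS)}")
    stat = _STATISTICS[statistic]
    observed = float(stat(build_sri_network(gbi_a), build_sri_network(gbi_b)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        na = build_sri_network(permute_gbi(gbi_a, rng))
        nb = build_sri_network(permute_gbi(gbi_b, rng))
        null[k] = stat(na, nb)
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm)
    return NullDistribution(statistic=statistic, observed=observed,
                            null_values=null, empirical_p=p)


def compare_networks(a: SocialNetwork, b: SocialNetwork,
                     n_perm: int = 1000, seed: int = 0) -> ComparisonResult:
    """All four similarity statistics between two networks."""
    coef, p_q = mrqap_simple(a, b, n_perm=n_perm, seed=seed)
    r, p_m = mantel(a, b, n_perm=min(n_perm, 999), seed=seed + 1)
    return ComparisonResult(
        jaccard_edges=jaccard_edges(a, b),
        jaccard_triangles=jaccard_triangles(a, b),
        mrqap_coef=coef, mrqap_p=p_q,
        mantel_r=r, mantel_p=p_m,
    )


def null_distributions_frame(dists: list[NullDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        for v in d.null_values:
            rows.append({"statistic": d.statistic, "null_value": v})
    return pd.DataFrame(rows)
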