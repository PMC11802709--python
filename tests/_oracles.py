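"""Independent brute-force oracles used to validate the implementations.

These deliberately use different algorithms from the library code:
union-find for the chain rule, exhaustive simple-path enumeration for
weighted betweenness, and direct triple/set arithmetic for the Jaccard
statistics.
"""

from itertools import combinations, permutations

import numpy as np


def union_find_groups(times, individuals, delta_t):
    """Connected components of the pairwise within-delta_t graph."""
    n = len(times)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, j in combinations(range(n), 2):
        if abs(times[i] - times[j]) <= delta_t:
            union(i, j)
    comps = {}
    for k in range(n):
        comps.setdefault(find(k), []).append(k)
    groups = []
    for members in comps.values():
        groups.append((min(times[m] for m in members),
                       frozenset(individuals[m] for m in members)))
    groups.sort()
    return [g[1] for g in groups]


def brute_betweenness(weights):
    """Geodesic betweenness on costs 1/w by enumerating all simple paths.

    Unnormalized, endpoints excluded, equal-cost geodesics split
    fractionally. Only feasible for ~7 nodes.
    """
    n = weights.shape[0]
    cost = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), np.inf)
    bet = np.zeros(n)
    for s, t in combinations(range(n), 2):
        others = [v for v in range(n) if v not in (s, t)]
        best = np.inf
        geodesics = []
        for k in range(len(others) + 1):
            for mid in permutations(others, k):
                path = (s, *mid, t)
                c = sum(cost[path[i], path[i + 1]] for i in range(len(path) - 1))
                if not np.isfinite(c):
                    continue
                if c < best - 1e-9:
                    best, geodesics = c, [path]
                elif abs(c - best) <= 1e-9:
                    geodesics.append(path)
        if not np.isfinite(best):
            continue
        for path in geodesics:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(geodesics)
    return bet


def brute_triangles(nodes, weights):
    """All closed node triples, by direct O(V^3) enumeration."""
    adj = weights > 0
    tri = set()
    for i, j, k in combinations(range(len(nodes)), 3):
        if adj[i, j] and adj[j, k] and adj[i, k]:
            tri.add(frozenset((nodes[i], nodes[j], nodes[k])))
    return tri


def arrivals_by_scan(times, delta_i):
    """Linear scan: count arrivals of one individual at one location."""
    count = 0
    prev = None
    for t in times:
        if prev is None or t - prev > delta_i:
            count += 1
        prev = t
    return count
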