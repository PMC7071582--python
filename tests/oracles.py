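"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) they validate: shortest paths are enumerated recursively,
hypergeometric tails use exact binomial coefficients, and AUC counts
pairwise comparisons directly.
"""

from __future__ import annotations

import itertools
from math import comb


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj: dict, s, t, dist):
    """Enumerate every shortest s->t path by recursive descent."""
    target_len = dist.get(t)
    if target_len is None:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in adj[u]:
            if dist.get(v) == len(path):  # stay on a shortest path
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_force_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bet = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        dist = bfs_distances(adj, s)
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bet[v] += through / len(paths)
    return bet


def brute_force_closeness(nodes, edges) -> dict:
    """Per-component closeness: (n_reachable - 1) / sum of distances."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for n in nodes:
        dist = bfs_distances(adj, n)
        total = sum(dist.values())
        out[n] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def hypergeom_upper_tail(a: int, set_size: int, n_pos: int, universe: int) -> float:
    """P(X >= a) for X ~ Hypergeom(universe, n_pos, set_size), exact."""
    denom = comb(universe, set_size)
    upper = min(set_size, n_pos)
    total = sum(
        comb(n_pos, x) * comb(universe - n_pos, set_size - x)
        for x in range(a, upper + 1)
    )
    return total / denom


def pairwise_auc(pos_scores, neg_scores) -> float:
    """AUC as the fraction of (pos, neg) pairs ordered correctly, ties 1/2."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
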