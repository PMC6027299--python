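"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration, direct
textbook formulas, BFS layer counting — and shares no code path with
the package.
"""
from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


# -- betweenness centrality ----------------------------------------------------


def bfs_paths(adj: dict, source) -> tuple[dict, dict]:
    """Shortest-path distances and path counts from one source (BFS + DP)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness via all-pairs path counting.

    For each unordered pair (s, t) and interior node i, a shortest s–t
    path passes through i iff d(s,i) + d(i,t) = d(s,t); the number of
    such paths is sigma_s(i) * sigma_i(t).
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = bfs_paths(adj, s)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        n_st = sigma[s][t]
        for i in nodes:
            if i in (s, t) or i not in dist[s] or i not in dist[t]:
                continue
            if dist[s][i] + dist[i][t] == d_st:
                bc[i] += sigma[s][i] * sigma[i][t] / n_st
    return bc


# -- Mann-Whitney --------------------------------------------------------------


def u_statistic(x, y) -> float:
    """U of sample x: number of (x_i, y_j) pairs with x_i > y_j (ties 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_exact_p(x, y) -> float:
    """Two-sided MWU p by exhaustive enumeration of all group labelings."""
    pooled = list(x) + list(y)
    nx = len(x)
    mean_u = nx * len(y) / 2.0
    observed = abs(u_statistic(x, y) - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        in_x = set(combo)
        gx = [pooled[i] for i in range(len(pooled)) if i in in_x]
        gy = [pooled[i] for i in range(len(pooled)) if i not in in_x]
        total += 1
        if abs(u_statistic(gx, gy) - mean_u) >= observed - 1e-12:
            hits += 1
    return hits / total


def mwu_permutation_p(x, y, n_perm: int, rng: np.random.Generator) -> float:
    """Monte-Carlo permutation two-sided MWU p-value."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    nx = len(x)
    mean_u = nx * len(y) / 2.0
    observed = abs(u_statistic(x, y) - mean_u)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(u_statistic(perm[:nx], perm[nx:]) - mean_u) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# -- Benjamini-Hochberg --------------------------------------------------------


def bh_textbook(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values, straight from the definition."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


# -- hypergeometric tail -------------------------------------------------------


def hypergeom_tail_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by enumerating every size-n draw from N items."""
    hits = total = 0
    marked = set(range(K))
    for combo in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(combo)) >= k:
            hits += 1
    return hits / total


# -- Pearson correlation -------------------------------------------------------


def pearson_two_pass(x, y) -> float:
    """Two-pass textbook Pearson correlation (no vectorized shortcuts)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - my) ** 2 for v in y) / (n - 1))
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / ((n - 1) * sx * sy)


# -- triples -------------------------------------------------------------------


def triples_triple_loop(pos_pairs, neg_lnc_mirna, neg_mrna_mirna):
    """All (l, m, g) combinations satisfying the three pair memberships."""
    pos = {(a, b) for a, b in pos_pairs}
    neg_l = {(a, b) for a, b in neg_lnc_mirna}
    neg_g = {(a, b) for a, b in neg_mrna_mirna}
    lncs = {a for a, _ in pos} | {a for a, _ in neg_l}
    mrnas = {b for _, b in pos} | {a for a, _ in neg_g}
    mirnas = {b for _, b in neg_l} | {b for _, b in neg_g}
    out = set()
    for l in lncs:
        for m in mirnas:
            for g in mrnas:
                if (l, g) in pos and (l, m) in neg_l and (g, m) in neg_g:
                    out.add((l, m, g))
    return out
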