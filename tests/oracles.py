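"""Independent reference implementations used only by the test suite.

These re-derive every quantity from first principles (matrix Floyd-Warshall,
exhaustive path enumeration, naive peeling, nested-loop formula evaluation)
so they share no code path with the package implementations they check.
"""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from eddc.graph import Graph


def floyd_warshall(g: Graph) -> np.ndarray:
    """O(N^3) all-pairs hop distances from the adjacency matrix."""
    n = g.N
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in g.neighbor_indices(i):
            d[i, j] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def _adj_sets(g: Graph) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes}


def all_simple_paths(adj: dict, a, b) -> list[tuple]:
    out = []
    stack = [(a, (a,))]
    while stack:
        u, path = stack.pop()
        if u == b:
            out.append(path)
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + (w,)))
    return out


def bc_exhaustive(g: Graph) -> dict:
    """Betweenness by enumerating every simple path of every pair (n <= 7)."""
    adj = _adj_sets(g)
    bc = {v: 0.0 for v in g.nodes}
    for a, b in combinations(g.nodes, 2):
        paths = all_simple_paths(adj, a, b)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in g.nodes:
            if v in (a, b):
                continue
            bc[v] += sum(1 for p in sp if v in p) / len(sp)
    return bc


def bc_pair_counting(g: Graph) -> dict:
    """Betweenness via per-pair shortest-path counts (sigma DP), no Brandes."""
    n = g.N
    d = floyd_warshall(g)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(range(n), key=lambda v: d[s, v])
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            sigma[s, v] = sum(
                sigma[s, w] for w in g.neighbor_indices(v) if d[s, w] == d[s, v] - 1
            )
    bc = {v: 0.0 for v in g.nodes}
    for a, b in combinations(range(n), 2):
        if not np.isfinite(d[a, b]) or sigma[a, b] == 0:
            continue
        for v in range(n):
            if v in (a, b):
                continue
            if d[a, v] + d[v, b] == d[a, b]:
                bc[g.label(v)] += sigma[a, v] * sigma[v, b] / sigma[a, b]
    return bc


def clustering_brute(g: Graph) -> dict:
    adj = _adj_sets(g)
    out = {}
    for v in g.nodes:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k <= 1:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def entropy_brute(g: Graph, v) -> float:
    degs = [g.degree(u) for u in g.neighbors(v)]
    if len(degs) <= 1:
        return 0.0
    s = sum(degs)
    return -sum(d / s * math.log2(d / s) for d in degs)


def lgc_naive(g: Graph) -> dict:
    d = floyd_warshall(g)
    out = {}
    for i, v in enumerate(g.nodes):
        total = 0.0
        for j, u in enumerate(g.nodes):
            if i != j and np.isfinite(d[i, j]):
                total += math.sqrt(g.degree(u)) / d[i, j]
        out[v] = g.degree(v) / g.N * total
    return out


def clgc_naive(g: Graph) -> dict:
    d = floyd_warshall(g)
    clc = clustering_brute(g)
    out = {}
    for i, v in enumerate(g.nodes):
        total = 0.0
        for j, u in enumerate(g.nodes):
            if i != j and np.isfinite(d[i, j]):
                total += math.sqrt(clc[u]) / d[i, j]
        out[v] = clc[v] * total
    return out


def eclgc_naive(g: Graph) -> dict:
    d = floyd_warshall(g)
    clc = clustering_brute(g)

    def local(v):
        nbrs = g.neighbors(v)
        if not nbrs:
            return clc[v]
        return clc[v] + sum(math.sqrt(clc[u]) for u in nbrs) / len(nbrs)

    out = {}
    for i, v in enumerate(g.nodes):
        total = 0.0
        for j, u in enumerate(g.nodes):
            if i != j and np.isfinite(d[i, j]):
                total += math.sqrt(local(u)) / d[i, j]
        out[v] = local(v) + total
    return out


def eddc_naive(g: Graph) -> dict:
    d = floyd_warshall(g)
    ent = {v: entropy_brute(g, v) for v in g.nodes}
    out = {}
    for i, v in enumerate(g.nodes):
        total = 0.0
        for j, u in enumerate(g.nodes):
            if i != j and np.isfinite(d[i, j]):
                total += math.sqrt(ent[v] + ent[u]) / d[i, j]
        out[v] = g.degree(v) / g.N * total
    return out


def kshell_naive(g: Graph) -> dict:
    """Iterative peeling, recomputing residual degrees from scratch each pass."""
    alive = set(g.nodes)
    adj = _adj_sets(g)
    shell = {}
    k = 0
    while alive:
        while True:
            res_deg = {v: len(adj[v] & alive) for v in alive}
            doomed = {v for v in alive if res_deg[v] <= k}
            if not doomed:
                break
            for v in doomed:
                shell[v] = k
            alive -= doomed
        k += 1
    return shell


def kendall_brute(x, y) -> float:
    """O(n^2) concordant/discordant pair counting, tau-a denominator."""
    n = len(x)
    nc = nd = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                nc += 1
            elif prod < 0:
                nd += 1
    return (nc - nd) / (0.5 * n * (n - 1))
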