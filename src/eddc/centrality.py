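"""Node-importance measures: eight baselines and the EDDC score.

The baselines are degree (DC), betweenness (BC), closeness (CC), clustering
coefficient (CLC), isolating centrality (ISC), local-global centrality (LGC),
k-shell, CLGC and ECLGC.  The package's own contribution is the
entropy-degree-distance combination

    EDDC(v) = (deg(v)/N) * sum_{j != v} sqrt(e(v) + e(j)) / dist(v, j)

where ``e(v)`` is the base-2 Shannon entropy of the distribution obtained by
normalizing the degrees of v's neighbors.  Unreachable nodes contribute 0 to
every inverse-distance sum.
"""
from __future__ import annotations

import math
from collections.abc import Hashable, Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import Graph, _label_sort_key, all_pairs_distances, bfs_distances

__all__ = [
    "ScoreTable",
    "RankList",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "clustering_coefficient",
    "isolating_centrality",
    "lgc",
    "k_shell",
    "clgc",
    "eclgc",
    "neighbor_probabilities",
    "node_entropy",
    "entropy_vector",
    "eddc_aggregate",
    "eddc",
    "rank_nodes",
    "METHODS",
    "compute_method",
]

#: Decimal places used when deciding whether two scores are "equal"
#: (monotonicity counting, rank tie-breaks); absorbs float noise.
SCORE_DECIMALS = 10


@dataclass(frozen=True)
class ScoreTable:
    """Per-node real-valued scores produced by one method."""

    method: str
    scores: dict[Hashable, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = [v for v, s in self.scores.items() if not math.isfinite(s)]
        if bad:
            raise ValueError(f"{self.method}: non-finite score for nodes {bad[:5]}")

    def array(self, order: Sequence[Hashable]) -> np.ndarray:
        """Scores aligned to the given node order."""
        return np.array([self.scores[v] for v in order], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.scores), "score": list(self.scores.values())}
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# method={self.method} params={self.params}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class RankList:
    """Total order of nodes, best first; rank is 1-based."""

    nodes: tuple[Hashable, ...]
    scores: dict[Hashable, float]
    method: str = ""

    @property
    def ranks(self) -> dict[Hashable, int]:
        return {v: r for r, v in enumerate(self.nodes, start=1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.nodes) + 1),
                "node": list(self.nodes),
                "score": [self.scores[v] for v in self.nodes],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# method={self.method}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def rank_nodes(table: ScoreTable) -> RankList:
    """Descending score; ties broken by ascending node label (deterministic)."""
    ordered = sorted(
        table.scores,
        key=lambda v: (-round(table.scores[v], SCORE_DECIMALS), _label_sort_key(v)),
    )
    return RankList(tuple(ordered), dict(table.scores), method=table.method)


# -- classical baselines ----------------------------------------------------


def degree_centrality(g: Graph) -> ScoreTable:
    """DC(v) = |Γ(v)|, the count of one-hop neighbors."""
    return ScoreTable("dc", {v: float(g.degree(v)) for v in g.nodes})


def betweenness_centrality(g: Graph) -> ScoreTable:
    """Unnormalized shortest-path betweenness over unordered node pairs."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return ScoreTable("bc", {v: float(bc[v]) for v in g.nodes})


def closeness_centrality(g: Graph) -> ScoreTable:
    """CC(v) = (N-1) / sum of distances to reachable nodes; isolated -> 0.

    The N-1 numerator is kept even on disconnected graphs (the printed form);
    unreachable nodes simply drop out of the sum.
    """
    dist = all_pairs_distances(g)
    scores = {}
    for i, v in enumerate(g.nodes):
        row = dist[i]
        finite = row[np.isfinite(row)]
        total = finite.sum()
        scores[v] = (g.N - 1) / total if total > 0 else 0.0
    return ScoreTable("cc", scores)


def clustering_coefficient(g: Graph) -> ScoreTable:
    """CLC(v) = 2|E(v)| / (deg(v)(deg(v)-1)); degree <= 1 nodes score 0."""
    cc = nx.clustering(g.to_networkx())
    return ScoreTable("clc", {v: float(cc[v]) for v in g.nodes})


def isolating_centrality(g: Graph, delta: int = 2) -> ScoreTable:
    """ISC(v) = |{u in Γ(v) : deg(u) >= delta}| * deg(v).

    Deg_delta is taken as the set of nodes with degree at least ``delta``: a
    high-degree node scores low when its neighbors fall below the threshold.
    The threshold convention lives in :func:`_meets_isc_threshold` so it can
    be swapped wholesale if a different reading is wanted.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    deg = {v: g.degree(v) for v in g.nodes}
    scores = {
        v: float(sum(_meets_isc_threshold(deg[u], delta) for u in g.neighbors(v)) * deg[v])
        for v in g.nodes
    }
    return ScoreTable("isc", scores, params={"delta": delta})


def _meets_isc_threshold(neighbor_degree: int, delta: int) -> bool:
    return neighbor_degree >= delta


def lgc(g: Graph) -> ScoreTable:
    """LGC(v) = (deg(v)/N) * sum_{j != v} sqrt(deg(j)) / dist(v, j)."""
    deg = g.degree_array()
    sqrt_deg = np.sqrt(deg.astype(float))
    scores = {}
    for i, v in enumerate(g.nodes):
        d = bfs_distances(g, v)
        mask = np.isfinite(d) & (d > 0)
        scores[v] = deg[i] / g.N * float((sqrt_deg[mask] / d[mask]).sum())
    return ScoreTable("lgc", scores)


def k_shell(g: Graph) -> ScoreTable:
    """Shell index from iterative peeling of residual degree <= k nodes."""
    gx = g.to_networkx()
    gx.remove_edges_from(nx.selfloop_edges(gx))
    core = nx.core_number(gx)
    return ScoreTable("kshell", {v: float(core[v]) for v in g.nodes})


def clgc(g: Graph) -> ScoreTable:
    """CLGC(v) = CLC(v) * sum_{j != v} sqrt(CLC(j)) / dist(v, j)."""
    clc = clustering_coefficient(g).array(g.nodes)
    sqrt_clc = np.sqrt(clc)
    scores = {}
    for i, v in enumerate(g.nodes):
        d = bfs_distances(g, v)
        mask = np.isfinite(d) & (d > 0)
        scores[v] = clc[i] * float((sqrt_clc[mask] / d[mask]).sum())
    return ScoreTable("clgc", scores)


def eclgc(g: Graph) -> ScoreTable:
    """Two-level clustering combination.

    Local term: CLC(v) + mean over neighbors of sqrt(CLC); global term: the
    sqrt of each other node's own local term, inverse-distance weighted.
    """
    clc = clustering_coefficient(g).array(g.nodes)
    sqrt_clc = np.sqrt(clc)
    local = np.empty(g.N)
    for i in range(g.N):
        nbrs = list(g.neighbor_indices(i))
        nb_term = sqrt_clc[nbrs].sum() / len(nbrs) if nbrs else 0.0
        local[i] = clc[i] + nb_term
    sqrt_local = np.sqrt(local)
    scores = {}
    for i, v in enumerate(g.nodes):
        d = bfs_distances(g, v)
        mask = np.isfinite(d) & (d > 0)
        scores[v] = local[i] + float((sqrt_local[mask] / d[mask]).sum())
    return ScoreTable("eclgc", scores)


# -- entropy and EDDC -------------------------------------------------------


def neighbor_probabilities(g: Graph, v: Hashable) -> dict[Hashable, float]:
    """p(u) = deg(u) / sum of neighbor degrees, over u in Γ(v)."""
    nbrs = g.neighbors(v)
    if not nbrs:
        raise ValueError(f"node {v!r} is isolated: no neighbor distribution exists")
    degs = np.array([g.degree(u) for u in nbrs], dtype=float)
    p = degs / degs.sum()
    return dict(zip(nbrs, p.tolist()))


def node_entropy(g: Graph, v: Hashable) -> float:
    """Base-2 Shannon entropy of v's neighbor-degree distribution.

    Degree-0 and degree-1 nodes score 0 (empty sum / point mass).
    """
    if g.degree(v) <= 1:
        return 0.0
    p = np.array(list(neighbor_probabilities(g, v).values()))
    return float(-(p * np.log2(p)).sum())


def entropy_vector(g: Graph) -> np.ndarray:
    """Entropies of all nodes in internal index order."""
    return np.array([node_entropy(g, v) for v in g.nodes])


def eddc_aggregate(
    deg_v: int,
    n_nodes: int,
    e_v: float,
    others: Iterable[tuple[float, float]],
) -> float:
    """Assemble the EDDC score from precomputed pieces.

    ``others`` holds ``(entropy, distance)`` pairs for every node other than
    v; infinite distances contribute 0.  Pure formula assembly, independent of
    any graph, so the bundled worked example can be checked term by term.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if e_v < 0:
        raise ValueError("entropy must be non-negative")
    total = 0.0
    for e_j, d in others:
        if e_j < 0:
            raise ValueError("entropy must be non-negative")
        if d < 1:
            raise ValueError("distance to another node must be >= 1")
        if math.isinf(d):
            continue
        total += math.sqrt(e_v + e_j) / d
    return deg_v / n_nodes * total


def eddc(g: Graph, max_hops: int | None = None) -> ScoreTable:
    """EDDC score for every node.

    ``max_hops`` enables the hop-limited approximation (BFS truncated at that
    radius); the default computes the exact inverse-distance sum.
    """
    ent = entropy_vector(g)
    deg = g.degree_array()
    scores = {}
    for i, v in enumerate(g.nodes):
        if deg[i] == 0:
            scores[v] = 0.0
            continue
        d = bfs_distances(g, v, max_hops=max_hops)
        mask = np.isfinite(d) & (d > 0)
        scores[v] = deg[i] / g.N * float((np.sqrt(ent[i] + ent[mask]) / d[mask]).sum())
    params = {} if max_hops is None else {"max_hops": max_hops}
    return ScoreTable("eddc", scores, params=params)


#: Registry of method name -> callable(graph, **params) used by the CLI and
#: the evaluation pipeline.
METHODS = {
    "dc": degree_centrality,
    "bc": betweenness_centrality,
    "cc": closeness_centrality,
    "clc": clustering_coefficient,
    "isc": isolating_centrality,
    "lgc": lgc,
    "kshell": k_shell,
    "clgc": clgc,
    "eclgc": eclgc,
    "eddc": eddc,
}


def compute_method(g: Graph, name: str, **params) -> ScoreTable:
    try:
        fn = METHODS[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; registered: {', '.join(sorted(METHODS))}"
        ) from None
    return fn(g, **params)
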