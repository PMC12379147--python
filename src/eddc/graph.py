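"""Undirected simple-graph container, edge-list I/O, and BFS shortest paths.

Every measure in this package operates on an unweighted, undirected simple
graph.  Nodes carry arbitrary hashable labels externally (the bundled toy
network uses 1-based integers) and contiguous 0-based indices internally; a
bidirectional label map keeps all reports in original labels.  Unreachable
distances are an explicit ``inf`` sentinel — downstream inverse-distance sums
treat ``1/inf`` as 0.
"""
from __future__ import annotations

import logging
from collections import deque
from collections.abc import Hashable, Iterable, Sequence
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "load_edge_list",
    "write_edge_list",
    "bfs_distances",
    "all_pairs_distances",
]


def _label_sort_key(label: Hashable) -> tuple:
    """Total order over possibly mixed-type labels: numbers first, then text."""
    if isinstance(label, bool):
        return (1, str(label))
    if isinstance(label, (int, float)):
        return (0, label, "")
    return (1, str(label))


class Graph:
    """Simple undirected graph: label list + symmetric adjacency sets.

    Self-loops and duplicate/reversed edges are dropped silently (counts are
    logged at INFO).  Construction asserts the structural invariants: symmetric
    adjacency, no loops, ``E`` equal to half the degree sum, ``N >= 1``.
    """

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable]],
        nodes: Sequence[Hashable] | None = None,
    ):
        labels: list[Hashable] = []
        index: dict[Hashable, int] = {}

        def idx(label: Hashable) -> int:
            i = index.get(label)
            if i is None:
                i = len(labels)
                index[label] = i
                labels.append(label)
            return i

        for label in nodes or ():
            idx(label)

        adj: list[set[int]] = [set() for _ in labels]
        loops = dupes = 0
        for u, v in edges:
            i, j = idx(u), idx(v)
            while len(adj) < len(labels):
                adj.append(set())
            if i == j:
                loops += 1
                continue
            if j in adj[i]:
                dupes += 1
                continue
            adj[i].add(j)
            adj[j].add(i)
        if loops or dupes:
            logger.info("graph cleanup: dropped %d self-loop(s), %d duplicate edge(s)", loops, dupes)
        if not labels:
            raise ValueError("graph must contain at least one node")

        self._labels: tuple[Hashable, ...] = tuple(labels)
        self._index = index
        self._adj: tuple[frozenset[int], ...] = tuple(frozenset(s) for s in adj)
        self._edge_count = sum(len(s) for s in self._adj) // 2
        # CSR-style neighbor arrays, used by the SIR simulator's hot loop.
        self._csr_indptr: np.ndarray | None = None
        self._csr_indices: np.ndarray | None = None
        assert all(i in self._adj[j] for i, s in enumerate(self._adj) for j in s)
        assert 2 * self._edge_count == sum(len(s) for s in self._adj)

    # -- basic accessors ---------------------------------------------------

    @property
    def N(self) -> int:
        return len(self._labels)

    @property
    def E(self) -> int:
        return self._edge_count

    @property
    def nodes(self) -> tuple[Hashable, ...]:
        """Node labels in internal index order."""
        return self._labels

    def index(self, label: Hashable) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node: {label!r}") from None

    def label(self, i: int) -> Hashable:
        return self._labels[i]

    def __contains__(self, label: Hashable) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return self.N

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(N={self.N}, E={self.E})"

    def neighbors(self, label: Hashable) -> tuple[Hashable, ...]:
        return tuple(self._labels[j] for j in self._adj[self.index(label)])

    def neighbor_indices(self, i: int) -> frozenset[int]:
        return self._adj[i]

    def degree(self, label: Hashable) -> int:
        """Number of one-hop neighbors |Γ(v)|."""
        return len(self._adj[self.index(label)])

    def degree_array(self) -> np.ndarray:
        """Degrees in internal index order."""
        return np.array([len(s) for s in self._adj], dtype=np.int64)

    def edges(self) -> list[tuple[Hashable, Hashable]]:
        """Edges with endpoints sorted by label, list sorted canonically."""
        out = []
        for i, s in enumerate(self._adj):
            for j in s:
                if i < j:
                    a, b = self._labels[i], self._labels[j]
                    if _label_sort_key(b) < _label_sort_key(a):
                        a, b = b, a
                    out.append((a, b))
        out.sort(key=lambda e: (_label_sort_key(e[0]), _label_sort_key(e[1])))
        return out

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (indptr, indices) neighbor arrays, built lazily and cached."""
        if self._csr_indptr is None:
            indptr = np.zeros(self.N + 1, dtype=np.int64)
            chunks = []
            for i, s in enumerate(self._adj):
                nbrs = np.fromiter(s, dtype=np.int64, count=len(s))
                nbrs.sort()
                chunks.append(nbrs)
                indptr[i + 1] = indptr[i] + len(s)
            self._csr_indptr = indptr
            self._csr_indices = (
                np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
            )
        return self._csr_indptr, self._csr_indices

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls(g.edges(), nodes=list(g.nodes()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._labels)
        for i, s in enumerate(self._adj):
            for j in s:
                if i < j:
                    g.add_edge(self._labels[i], self._labels[j])
        return g


# -- file I/O ---------------------------------------------------------------


def load_edge_list(path: str | Path, dialect: str = "auto") -> Graph:
    """Read a plain-text edge list into a :class:`Graph`.

    One edge per line, first two tokens are the endpoints; ``%`` / ``#``
    comment lines are skipped, as is the size-header line of a MatrixMarket
    (``%%MatrixMarket``) file.  ``dialect`` is ``"auto"`` (comma if the line
    contains one, else whitespace), ``"comma"`` or ``"whitespace"``.  Labels
    are parsed as ints when every label in the file is an integer literal.
    Self-loops and duplicate/reversed edges are dropped; directed inputs are
    thereby symmetrized.
    """
    path = Path(path)
    raw_edges: list[tuple[str, str]] = []
    is_mtx = False
    size_line_pending = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if lineno == 1 and stripped.startswith("%%MatrixMarket"):
                is_mtx = True
                size_line_pending = True
                continue
            if not stripped or stripped[0] in "%#":
                continue
            if dialect == "comma" or (dialect == "auto" and "," in stripped):
                tokens = [t for t in stripped.replace(",", " ").split() if t]
            else:
                tokens = stripped.split()
            if is_mtx and size_line_pending:
                size_line_pending = False
                if len(tokens) == 3:  # rows cols nnz header
                    continue
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line: {line.rstrip()!r}")
            raw_edges.append((tokens[0], tokens[1]))
    if not raw_edges:
        raise ValueError(f"{path}: no edges found")

    def _intable(tok: str) -> bool:
        try:
            int(tok)
        except ValueError:
            return False
        return True

    if all(_intable(t) for e in raw_edges for t in e):
        edges: list[tuple[Hashable, Hashable]] = [(int(u), int(v)) for u, v in raw_edges]
    else:
        edges = list(raw_edges)
    g = Graph(edges)
    if g.E == 0:
        raise ValueError(f"{path}: graph is empty after cleanup (no valid edges)")
    return g


def write_edge_list(g: Graph, path: str | Path) -> None:
    """Write the canonical edge list: sorted endpoint pairs, original labels."""
    with Path(path).open("w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


# -- shortest paths ---------------------------------------------------------


def bfs_distances(g: Graph, source: Hashable, max_hops: int | None = None) -> np.ndarray:
    """Hop distances from ``source`` to all nodes, in internal index order.

    Unreachable nodes get ``inf``.  ``max_hops`` truncates the frontier (used
    for the hop-limited approximation on large graphs); default ``None`` keeps
    the exact distances.
    """
    dist = np.full(g.N, np.inf)
    s = g.index(source)
    dist[s] = 0.0
    queue = deque([s])
    while queue:
        u = queue.popleft()
        du = dist[u]
        if max_hops is not None and du >= max_hops:
            continue
        for w in g.neighbor_indices(u):
            if dist[w] == np.inf:
                dist[w] = du + 1.0
                queue.append(w)
    return dist


def all_pairs_distances(g: Graph, max_hops: int | None = None) -> np.ndarray:
    """N x N symmetric hop-distance table; row i is BFS from node index i."""
    out = np.empty((g.N, g.N))
    for i in range(g.N):
        out[i] = bfs_distances(g, g.label(i), max_hops=max_hops)
    return out
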