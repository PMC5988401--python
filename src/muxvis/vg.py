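"""Visibility graphs of scalar time series.

A visibility graph maps a uniformly sampled series ``y_0 .. y_{N-1}`` onto a
graph whose nodes are the time indices.  Two variants are supported:

natural (NVG)
    ``i`` and ``j`` are linked iff the straight segment between
    ``(i, y_i)`` and ``(j, y_j)`` passes strictly above every intermediate
    sample: ``y_k < y_i + (y_j - y_i) * (k - i) / (j - i)`` for all
    ``i < k < j``.

horizontal (HVG)
    ``i`` and ``j`` are linked iff every intermediate sample is strictly
    smaller than both endpoints: ``y_k < min(y_i, y_j)``.

Both graphs are simple and undirected, always contain the chain of
consecutive-index edges, and the HVG is a subgraph of the NVG of the same
series.  All inequalities are strict: tied values block horizontal
visibility and collinear points block natural visibility, so the NVG is
invariant under addition of a linear trend and the HVG under any strictly
increasing rescaling of the values.

Node ids are 0-based positions in time order throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VisibilityGraph",
    "nvg_naive",
    "nvg_fast",
    "hvg",
    "degree_sequence",
    "nvg_degree_matrix",
    "hvg_degree_matrix",
    "write_edgelist",
    "write_adjacency",
]


def _validate_series(values) -> np.ndarray:
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {y.shape}")
    if y.size < 2:
        raise ValueError(f"series must have at least 2 points, got {y.size}")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    return y


@dataclass(frozen=True)
class VisibilityGraph:
    """Undirected simple graph on time-index nodes 0..n_nodes-1.

    ``edges`` is a lexicographically sorted ``(E, 2)`` integer array with
    ``i < j`` in every row; this pair list is the canonical representation,
    the adjacency matrix is only an exported view.
    """

    n_nodes: int
    edges: np.ndarray = field(repr=False)
    method: str  # "natural" | "horizontal"

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        e = e[np.lexsort((e[:, 1], e[:, 0]))]
        object.__setattr__(self, "edges", e)
        if self.method not in ("natural", "horizontal"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def degree_sequence(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency-matrix view."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        a[self.edges[:, 0], self.edges[:, 1]] = 1
        a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


def nvg_naive(series) -> VisibilityGraph:
    """Natural visibility graph by the exact O(N^2) scan.

    For each left endpoint ``i`` the candidates ``j`` are swept rightwards
    while maintaining the running maximum of the slope ``(y_k - y_i)/(k - i)``;
    ``j`` is visible from ``i`` exactly when its slope strictly exceeds every
    earlier one.  This is a literal restatement of the visibility criterion
    and serves as the oracle for :func:`nvg_fast`.
    """
    y = _validate_series(series)
    n = y.size
    rows = []
    for i in range(n - 1):
        slopes = (y[i + 1:] - y[i]) / np.arange(1, n - i)
        vis = np.empty(slopes.size, dtype=bool)
        vis[0] = True  # adjacent pair: no intermediate point
        if slopes.size > 1:
            vis[1:] = slopes[1:] > np.maximum.accumulate(slopes)[:-1]
        js = i + 1 + np.flatnonzero(vis)
        rows.append(np.column_stack([np.full(js.size, i), js]))
    return VisibilityGraph(n, np.concatenate(rows), "natural")


def nvg_fast(series) -> VisibilityGraph:
    """Natural visibility graph by divide and conquer.

    On a segment the maximum blocks every line of sight across it, so only
    edges incident to the maximum can span it: those are collected by two
    running-max-slope sweeps away from the maximum, and the two flanking
    sub-segments are processed independently.  Expected O(N log N); the edge
    set is identical to :func:`nvg_naive` on every input.
    """
    y = _validate_series(series)
    n = y.size
    ei: list[int] = []
    ej: list[int] = []
    yl = y.tolist()  # python floats: much faster scalar sweeps
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        k = lo + int(np.argmax(y[lo:hi + 1]))  # leftmost maximum
        yk = yl[k]
        # leftward sweep: i sees k iff its slope towards k beats all closer ones
        best = -np.inf
        for i in range(k - 1, lo - 1, -1):
            u = (yl[i] - yk) / (k - i)
            if u > best:
                ei.append(i)
                ej.append(k)
                best = u
        # rightward sweep
        best = -np.inf
        for j in range(k + 1, hi + 1):
            u = (yl[j] - yk) / (j - k)
            if u > best:
                ei.append(k)
                ej.append(j)
                best = u
        if k - lo > 1:
            stack.append((lo, k - 1))
        if hi - k > 1:
            stack.append((k + 1, hi))
    return VisibilityGraph(n, np.column_stack([ei, ej]), "natural")


def hvg(series) -> VisibilityGraph:
    """Horizontal visibility graph by the O(N) monotone-stack scan.

    The stack holds indices whose values strictly decrease; a new point links
    to every popped smaller value and to the first value at least as large.
    An exact tie is linked once and then popped, since equal heights block
    all further visibility past the newer point.
    """
    y = _validate_series(series)
    n = y.size
    ei: list[int] = []
    ej: list[int] = []
    yl = y.tolist()
    stack: list[int] = []
    for t in range(n):
        yt = yl[t]
        while stack and yl[stack[-1]] < yt:
            ei.append(stack.pop())
            ej.append(t)
        if stack:
            ei.append(stack[-1])
            ej.append(t)
            if yl[stack[-1]] == yt:
                stack.pop()
        stack.append(t)
    return VisibilityGraph(n, np.column_stack([ei, ej]), "horizontal")


def degree_sequence(graph: VisibilityGraph) -> np.ndarray:
    """Degree of each time-index node, in node order; sums to 2|E|."""
    return graph.degree_sequence()


def nvg_degree_matrix(data) -> np.ndarray:
    """NVG degree sequences of every column of a T x M matrix at once.

    Returns an ``(N, M)`` integer array whose column ``m`` equals
    ``nvg_naive(data[:, m]).degree_sequence()``.  The sweep over left
    endpoints is shared across columns, which makes whole-multiplex degree
    extraction (all interlayer-MI inputs) one vectorised pass.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {y.shape}")
    n, m = y.shape
    if n < 2:
        raise ValueError("need at least 2 time points")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input matrix")
    deg = np.zeros((n, m), dtype=np.int64)
    for i in range(n - 1):
        slopes = (y[i + 1:] - y[i]) / np.arange(1, n - i)[:, None]
        vis = np.empty(slopes.shape, dtype=bool)
        vis[0] = True
        if slopes.shape[0] > 1:
            vis[1:] = slopes[1:] > np.maximum.accumulate(slopes, axis=0)[:-1]
        deg[i] += vis.sum(axis=0)
        deg[i + 1:] += vis
    return deg


def hvg_degree_matrix(data) -> np.ndarray:
    """HVG counterpart of :func:`nvg_degree_matrix` (per-column stack scans)."""
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {y.shape}")
    return np.column_stack([hvg(y[:, m]).degree_sequence() for m in range(y.shape[1])])


def write_edgelist(graph: VisibilityGraph, path) -> None:
    """Two-column 0-based integer CSV with header ``i,j`` and i < j rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j"])
        w.writerows(graph.edges.tolist())


def write_adjacency(graph: VisibilityGraph, path) -> None:
    """Dense 0/1 adjacency CSV (no header), one row per node."""
    np.savetxt(path, graph.adjacency(), fmt="%d", delimiter=",")
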