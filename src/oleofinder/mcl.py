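"""Markov Cluster (MCL) algorithm on weighted undirected graphs.

MCL simulates flow on a graph: the column-stochastic transition matrix is
alternately expanded (matrix power) and inflated (entrywise power followed
by re-normalisation) until it converges to a doubly idempotent attractor
structure from which clusters are read off.  Inflation strengthens strong
flows and weakens weak ones; higher inflation yields finer clusterings.

The implementation is sparse throughout so that correlation graphs with a
few thousand nodes cluster in seconds, and is fully deterministic: node
ordering is by sorted identifier and the attractor tie-break is
lexicographic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["ClusterSet", "mcl", "column_normalize", "read_graph_tsv",
           "write_graph_tsv", "write_clusters_tsv"]


@dataclass
class ClusterSet:
    """A disjoint partition of graph nodes plus the nodes left unclustered.

    ``clusters`` are sorted internally by node id and ordered by their
    smallest member, so two runs on the same graph compare equal.
    """

    clusters: list[list] = field(default_factory=list)
    unclustered: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not c for c in self.clusters):
            raise ValueError("empty cluster")
        self.clusters = [sorted(c, key=str) for c in self.clusters]
        self.clusters.sort(key=lambda c: str(c[0]))
        self.unclustered = sorted(self.unclustered, key=str)
        seen: set = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & set(c):
                raise ValueError("clusters are not disjoint")
            seen |= set(c)
        if seen & set(self.unclustered):
            raise ValueError("unclustered nodes overlap clusters")

    @property
    def n_nodes(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.unclustered)

    def labels(self) -> dict:
        """Node -> cluster index (unclustered nodes map to -1)."""
        out = {}
        for i, c in enumerate(self.clusters):
            for node in c:
                out[node] = i
        for node in self.unclustered:
            out[node] = -1
        return out

    def as_sets(self) -> list[frozenset]:
        return [frozenset(c) for c in self.clusters]


def column_normalize(matrix: np.ndarray) -> np.ndarray:
    """Scale each column of a non-negative matrix to sum to one.

    Raises ``ValueError`` on negative entries or an all-zero column.
    """
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("matrix has negative entries")
    sums = m.sum(axis=0)
    if (sums == 0).any():
        bad = np.nonzero(sums == 0)[0]
        raise ValueError(f"all-zero column(s) at index {bad.tolist()}")
    return m / sums


def _normalize_sparse(m: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    if (sums == 0).any():
        raise ValueError("all-zero column during MCL iteration")
    return (m @ sp.diags(1.0 / sums)).tocsr()


def _adjacency(graph: nx.Graph, nodes: Sequence[Hashable]) -> sp.csr_matrix:
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols, data = [], [], []
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        if u == v:
            continue
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    n = len(nodes)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loops: bool = True,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterSet:
    """Cluster a weighted undirected graph with the MCL process.

    Parameters
    ----------
    graph:
        ``networkx.Graph``; missing ``weight`` attributes default to 1.
    inflation:
        Entrywise power applied after each expansion; must exceed 1.
        2.0 is the classic default; OrthoMCL historically used 1.5.
    expansion:
        Matrix-power exponent (>= 2).
    self_loops:
        Add a loop to every node with weight equal to its maximum incident
        edge weight, which damps odd/even flow oscillation.
    prune_threshold:
        Entries below this value are zeroed after inflation, keeping the
        matrix sparse.
    max_iter, tol:
        Iteration stops when the largest entrywise change falls below
        ``tol`` or after ``max_iter`` rounds (the latter with a warning).

    Returns
    -------
    ClusterSet
        Isolated input nodes are reported in ``unclustered``; every
        connected node lands in exactly one cluster.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")

    nodes = sorted(graph.nodes, key=str)
    A = _adjacency(graph, nodes)
    degree = np.asarray((A != 0).sum(axis=0)).ravel()
    isolated = [v for v, d in zip(nodes, degree) if d == 0]
    live = [v for v, d in zip(nodes, degree) if d > 0]
    if not live:
        return ClusterSet(clusters=[], unclustered=isolated)
    keep = np.nonzero(degree > 0)[0]
    A = A[np.ix_(keep, keep)].tocsr()

    if self_loops:
        loop = np.asarray(A.max(axis=0).todense()).ravel()
        A = A + sp.diags(loop)

    M = _normalize_sparse(A.tocsr())
    converged = False
    for _ in range(max_iter):
        prev = M.copy()
        # expand
        P = M
        for _ in range(expansion - 1):
            P = (P @ M).tocsr()
        M = P
        # inflate + prune + renormalise; pruning never empties a column
        # (each column keeps at least its maximum entry)
        M = M.tocsc(copy=True)
        M.data = np.power(M.data, inflation)
        colmax = np.asarray(M.max(axis=0).todense()).ravel()
        keep_floor = np.minimum(colmax, prune_threshold)
        for j in range(M.shape[1]):
            lo, hi = M.indptr[j], M.indptr[j + 1]
            col = M.data[lo:hi]
            col[col < keep_floor[j]] = 0.0
        M.eliminate_zeros()
        M = _normalize_sparse(M.tocsr())
        delta = abs(M - prev)
        if delta.nnz == 0 or delta.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "clusters read from current state", stacklevel=2)

    clusters_idx = _interpret(M)
    clusters = [[live[i] for i in c] for c in clusters_idx]
    return ClusterSet(clusters=clusters, unclustered=isolated)


def _interpret(M: sp.csr_matrix) -> list[list[int]]:
    """Read clusters from a converged MCL matrix.

    Attractors are nodes with positive diagonal mass.  Attractor systems
    (attractors linked by flow) form the cluster cores; every other node
    joins the system of the lexicographically smallest attractor it flows
    to (deterministic tie-break for nodes attracted to several systems).
    """
    n = M.shape[0]
    coo = M.tocoo()
    diag = M.diagonal()
    attractors = np.nonzero(diag > 0)[0]
    att_set = set(attractors.tolist())

    # union attractors that share flow
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    attracted_to: dict[int, list[int]] = {}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if v <= 0:
            continue
        if i in att_set and j in att_set and i != j:
            union(i, j)
        if i in att_set:
            attracted_to.setdefault(j, []).append(i)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)

    assignment: dict[int, int] = {}
    for a in attractors:
        assignment[a] = find(a)
    for j in range(n):
        if j in assignment:
            continue
        pulls = attracted_to.get(j)
        if not pulls:
            # no attractor mass reaches this node; it anchors itself
            assignment[j] = j
            continue
        assignment[j] = find(min(pulls))

    out: dict[int, list[int]] = {}
    for j, root in assignment.items():
        out.setdefault(root, []).append(j)
    return [sorted(v) for v in out.values()]


# ---------------------------------------------------------------------------
# graph / cluster I/O: 3-column edge TSV and 2-column cluster TSV

def read_graph_tsv(path) -> nx.Graph:
    """Read an edge list ``node_a<TAB>node_b<TAB>weight`` into a graph."""
    g = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            u, v, w = parts
            g.add_edge(u, v, weight=float(w))
    return g


def write_graph_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tcluster_id\n")
        for i, c in enumerate(clusters.clusters):
            for node in c:
                fh.write(f"{node}\t{i}\n")
        for node in clusters.unclustered:
            fh.write(f"{node}\t-1\n")
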