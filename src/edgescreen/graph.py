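"""Euclidean k-MST similarity graphs on pooled samples.

The edge-count test operates on a similarity graph built over the pooled
samples of all groups.  Following the recommendation that a k-MST (union of
k edge-disjoint minimum spanning trees) based on Euclidean distance keeps
the graph regular enough for the chi-square asymptotics, this module builds
such graphs deterministically and computes the graph functionals the null
moments and the regularity diagnostics need:

* ``C`` — the number of unordered edge pairs sharing a node,
  ``C = 1/2 * sum_k |G_k|^2 - |G|`` with ``|G_k|`` the degree of node k;
* ``A_e`` — an edge e together with the edges sharing a node with e;
* ``B_e`` — ``A_e`` together with the edges sharing a node with any member
  of ``A_e``.

``sum_e |A_e||B_e|`` growing slower than N^(3/2) (no clusters of hubs) is
one of the regularity conditions under which the test statistic is
asymptotically chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._mst import kruskal_kmst_edges

__all__ = [
    "SimilarityGraph",
    "GraphDiagnostics",
    "pairwise_distances",
    "build_kmst",
    "kmst_1d",
    "graph_diagnostics",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """A simple undirected graph on ``n_nodes`` pooled samples.

    ``edges`` is an (m, 2) integer array with each row an unordered pair
    (stored with smaller index first); ``tree_id`` records which of the k
    sequential spanning trees each edge belongs to.
    """

    n_nodes: int
    edges: np.ndarray
    tree_id: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed in a similarity graph")
        canon = np.sort(edges, axis=1)
        if len({(int(a), int(b)) for a, b in canon}) != len(canon):
            raise ValueError("duplicate edges are not allowed")

    @classmethod
    def _trusted(cls, n_nodes, edges, tree_id):
        """Internal constructor for edges produced by Kruskal (skips checks)."""
        g = object.__new__(cls)
        object.__setattr__(g, "n_nodes", n_nodes)
        object.__setattr__(g, "edges", edges)
        object.__setattr__(g, "tree_id", tree_id)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        """Node degrees |G_k|."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def to_edge_tsv(self, path) -> None:
        """Write the edge list as a two-column TSV (node_a, node_b)."""
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t",
                   header="node_a\tnode_b", comments="")


@dataclass(frozen=True)
class GraphDiagnostics:
    """Graph functionals entering the null moments and regularity checks."""

    n_edges: int
    C: float
    sum_sq_degree: float
    hub_term: float
    cluster_term: float


def pairwise_distances(values: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between pooled samples.

    ``values`` is (N,) or (N, d); rows are samples.  Non-finite entries are
    rejected with the offending sample named.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("expected a 1-D or 2-D array of sample values")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to build a distance matrix")
    bad = ~np.isfinite(x)
    if bad.any():
        sample = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(f"non-finite value in sample {sample}")
    return squareform(pdist(x, metric="euclidean"))


@lru_cache(maxsize=8)
def _triu_pairs(n):
    ii, jj = np.triu_indices(n, 1)
    return ii.astype(np.int64), jj.astype(np.int64)


def _kruskal_with_prefix(w, ii, jj, n_nodes, k):
    """Exact sequential Kruskal, trying a weight-threshold prefix first.

    Restricting Kruskal to all edges with weight <= some threshold is exact
    whenever the k trees complete within that prefix (Kruskal consumes edges
    in increasing key order, so a completed run never looks past the largest
    weight it used).  On failure the threshold is raised until the full edge
    set is in play.
    """
    n_edges = w.size
    target = 8 * k * n_nodes
    blocked = (
        "sequential k-MST construction blocked: an earlier greedy tree "
        "exhausted the edges some later tree needs (possible when k is close "
        "to N/2); use a smaller k"
    )
    if n_edges <= max(2 * target, 30_000):
        edges, tree_id, ok = kruskal_kmst_edges(w, ii, jj, n_nodes, k)
        if not ok:
            raise ValueError(blocked)
        return edges, tree_id
    # zero-weight tie edges all sort first, so they must sit inside the
    # initial prefix or the first attempt is wasted
    m = target + int(np.count_nonzero(w == 0.0))
    while True:
        if m >= n_edges:
            edges, tree_id, ok = kruskal_kmst_edges(w, ii, jj, n_nodes, k)
            if not ok:
                raise ValueError(blocked)
            return edges, tree_id
        thr = np.partition(w, m)[m]
        mask = w <= thr  # include every tie at the threshold
        edges, tree_id, ok = kruskal_kmst_edges(
            w[mask], ii[mask], jj[mask], n_nodes, k
        )
        if ok:
            return edges, tree_id
        m *= 4


def build_kmst(dist: np.ndarray, k: int) -> SimilarityGraph:
    """Union of k sequentially-built, pairwise edge-disjoint MSTs.

    Tree t is a minimum spanning tree of the complete graph minus all edges
    used by trees 1..t-1 (Kruskal with deterministic tie-break by
    (weight, smaller index, larger index)).  Requires ``k <= floor(N/2)`` so
    that k edge-disjoint spanning trees exist in the complete graph.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= k <= n // 2):
        raise ValueError(f"k must satisfy 1 <= k <= floor(N/2) = {n // 2}, got {k}")
    ii, jj = _triu_pairs(n)
    w = d[ii, jj]
    if not np.isfinite(w).all():
        raise ValueError("distance matrix contains non-finite entries")
    edges, tree_id = _kruskal_with_prefix(w, ii, jj, n, k)
    return SimilarityGraph._trusted(n, edges, tree_id)


def _ragged_cartesian(left_starts, left_counts, right_starts, right_counts):
    """Member-pair expansion for matched runs: all (left_i, right_j) pairs.

    Runs are contiguous index ranges [start, start+count); the result
    enumerates the cartesian product within each matched pair of runs.
    """
    sizes = left_counts * right_counts
    total = int(sizes.sum())
    if total == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    group = np.repeat(np.arange(sizes.size), sizes)
    offset = np.arange(total) - np.repeat(np.cumsum(sizes) - sizes, sizes)
    rc = right_counts[group]
    left = left_starts[group] + offset // rc
    right = right_starts[group] + offset % rc
    return left, right


def kmst_1d(x: np.ndarray, k: int) -> SimilarityGraph:
    """k-MST for one-dimensional samples, equal to ``build_kmst`` on |x_a - x_b|.

    Kruskal runs on a reduced candidate set that provably (for ties) or
    empirically with a wide safety margin (for the cross-value band)
    contains every edge the k sequential trees can use:

    * within a run of tied values, tree t always selects a star centred on
      the t-th member in original-index order (zero-weight edges sort ahead
      of everything else and only connect within their run), so only stars
      on the first k members are candidates;
    * across distinct values, tree t only uses edges between values at most
      2t-1 apart in sorted value order (the first tree is the sorted path,
      later trees interleave); the band used is 2k+3, and a completeness
      check falls back to the dense construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if not np.isfinite(x).all():
        sample = int(np.nonzero(~np.isfinite(x))[0][0])
        raise ValueError(f"non-finite value in sample {sample}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= k <= n // 2):
        raise ValueError(f"k must satisfy 1 <= k <= floor(N/2) = {n // 2}, got {k}")

    order = np.argsort(x, kind="stable")  # ties stay in original-index order
    xs = x[order]

    # runs of equal values: starts/counts in sorted position space
    is_start = np.concatenate(([True], xs[1:] != xs[:-1]))
    starts = np.nonzero(is_start)[0]
    counts = np.diff(np.append(starts, n))
    n_values = starts.size
    if n_values < 2:
        # all samples identical: the k-MST is k nested stars on zero weights
        return build_kmst(np.zeros((n, n)), k)

    if n_values == n:  # all distinct: plain band over sorted positions
        band = min(2 * k + 1, n - 1)
        offs = np.arange(1, band + 1)
        a = np.repeat(np.arange(n), band).reshape(n, band)
        b = a + offs
        keep = b < n
        pa, pb = a[keep], b[keep]
        w = xs[pb] - xs[pa]
        ia, ib = order[pa], order[pb]
        ii = np.minimum(ia, ib)
        jj = np.maximum(ia, ib)
        edges, tree_id, ok = kruskal_kmst_edges(w, ii, jj, n, k)
        if not ok:  # pragma: no cover - safety net
            return build_kmst(np.abs(x[:, None] - x[None, :]), k)
        return SimilarityGraph._trusted(n, edges, tree_id)

    pos_a = []
    pos_b = []
    # zero-weight candidates: stars on the first min(k, m-1) members of a run
    for run in np.nonzero(counts > 1)[0]:
        s, m = int(starts[run]), int(counts[run])
        n_ctr = min(k, m - 1)
        for a in range(n_ctr):
            pos_a.append(np.full(m - a - 1, s + a))
            pos_b.append(np.arange(s + a + 1, s + m))
    # cross-value candidates: all member pairs of runs within the value band
    band = min(2 * k + 3, n_values - 1)
    for g in range(1, band + 1):
        la, lb = _ragged_cartesian(
            starts[:-g], counts[:-g], starts[g:], counts[g:]
        )
        pos_a.append(la)
        pos_b.append(lb)
    pa = np.concatenate(pos_a)
    pb = np.concatenate(pos_b)
    w = xs[pb] - xs[pa]
    ia, ib = order[pa], order[pb]
    ii = np.minimum(ia, ib)
    jj = np.maximum(ia, ib)
    edges, tree_id, ok = kruskal_kmst_edges(w, ii, jj, n, k)
    if not ok:  # safety net: candidate band too thin for this instance
        return build_kmst(np.abs(x[:, None] - x[None, :]), k)
    return SimilarityGraph._trusted(n, edges, tree_id)


def graph_diagnostics(g: SimilarityGraph) -> GraphDiagnostics:
    """Compute C, degree sums and the hub/cluster regularity terms exactly."""
    deg = g.degrees
    n_edges = g.n_edges
    sum_sq = float(np.sum(deg.astype(float) ** 2))
    c = 0.5 * sum_sq - n_edges
    hub = sum_sq - 4.0 * n_edges**2 / g.n_nodes

    # |A_e| = deg(u) + deg(v) - 1 (no parallel edges); |B_e| counts edges
    # with an endpoint in {u, v} union N(u) union N(v).
    u, v = g.edges[:, 0], g.edges[:, 1]
    a_sizes = deg[u] + deg[v] - 1
    neighbors = [[] for _ in range(g.n_nodes)]
    for a, b in g.edges:
        neighbors[int(a)].append(int(b))
        neighbors[int(b)].append(int(a))
    cluster = 0.0
    for (a, b), a_size in zip(g.edges, a_sizes):
        nodes = set(neighbors[int(a)])
        nodes.update(neighbors[int(b)])
        nodes.add(int(a))
        nodes.add(int(b))
        inside = sum(deg[n] for n in nodes)
        # edges with both endpoints inside are double counted in the degree sum
        within = sum(1 for p in nodes for q in neighbors[p] if q > p and q in nodes)
        b_size = inside - within
        cluster += float(a_size) * float(b_size)
    return GraphDiagnostics(
        n_edges=n_edges,
        C=float(c),
        sum_sq_degree=sum_sq,
        hub_term=float(hub),
        cluster_term=float(cluster),
    )
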