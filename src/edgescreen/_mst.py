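"""Low-level Kruskal kernels for sequential (edge-disjoint) minimum spanning trees.

The similarity graph used by the edge-count test is a k-MST: the union of k
pairwise edge-disjoint spanning trees built sequentially, tree t being a
minimum spanning tree of the complete graph with the edges of trees 1..t-1
removed.  Edge order is (weight, smaller index, larger index), which fixes a
deterministic result even when distances tie.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sequential_kruskal(order, ii, jj, n_nodes, k):
    """Run k rounds of Kruskal over edges pre-sorted by (weight, i, j).

    Returns (edges, tree_id, n_found): ``edges`` is an (m, 2) array of the
    selected node pairs, ``tree_id`` the 0-based index of the tree each edge
    belongs to, and ``n_found`` the number of completed trees (== k on
    success; fewer if the supplied edge set cannot complete a tree, in which
    case the caller must retry with more candidate edges).
    """
    n_edges = order.size
    used = np.zeros(n_edges, np.bool_)
    out = np.empty((k * (n_nodes - 1), 2), np.int64)
    tree_id = np.empty(k * (n_nodes - 1), np.int64)
    pos = 0
    for t in range(k):
        parent = np.arange(n_nodes)
        count = 0
        for idx in range(n_edges):
            e = order[idx]
            if used[e]:
                continue
            a = ii[e]
            b = jj[e]
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            while parent[b] != b:
                parent[b] = parent[parent[b]]
                b = parent[b]
            if a != b:
                parent[a] = b
                used[e] = True
                out[pos, 0] = ii[e]
                out[pos, 1] = jj[e]
                tree_id[pos] = t
                pos += 1
                count += 1
                if count == n_nodes - 1:
                    break
        if count < n_nodes - 1:
            return out[:pos], tree_id[:pos], t
    return out, tree_id, k


def kruskal_kmst_edges(w, ii, jj, n_nodes, k):
    """Sort candidate edges by (w, i, j) and run sequential Kruskal.

    Returns (edges, tree_id, ok); ok is False when the candidate set is too
    sparse to complete all k trees.
    """
    order = np.lexsort((jj, ii, w))
    edges, tree_id, n_found = _sequential_kruskal(
        order, np.ascontiguousarray(ii), np.ascontiguousarray(jj), n_nodes, k
    )
    return edges, tree_id, n_found == k
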