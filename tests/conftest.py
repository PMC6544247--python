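"""Shared fixtures and independent oracle helpers for the test suite."""

import itertools

import numpy as np
import pytest

from edgescreen.graph import SimilarityGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def path5():
    """Path graph 0-1-2-3-4 (the 1-2-3-4-5 hand example, zero-based)."""
    return SimilarityGraph(n_nodes=5, edges=np.array([[0, 1], [1, 2], [2, 3], [3, 4]]))


def enumerate_label_assignments(n, sizes):
    """All distinct arrangements of a label multiset over n positions."""
    labels = np.concatenate([np.full(s, j) for j, s in enumerate(sizes)])
    seen = set()
    for perm in itertools.permutations(labels):
        seen.add(perm)
    return [np.array(p) for p in sorted(seen)]


def within_counts_bruteforce(edges, y, n_groups):
    """Naive double loop over edges counting same-group endpoints."""
    R = np.zeros(n_groups, dtype=int)
    for a, b in edges:
        if y[a] == y[b]:
            R[y[a]] += 1
    return R


def moments_by_enumeration(g, sizes):
    """Exact E(R) and Cov(R) by enumerating every label arrangement."""
    assignments = enumerate_label_assignments(g.n_nodes, sizes)
    Rs = np.array([
        within_counts_bruteforce(g.edges, y, len(sizes)) for y in assignments
    ], dtype=float)
    mean = Rs.mean(axis=0)
    cov = (Rs - mean).T @ (Rs - mean) / len(Rs)
    return mean, cov


def min_spanning_weight_bruteforce(dist):
    """Minimum spanning-tree weight by enumerating all edge subsets (N <= 6)."""
    n = dist.shape[0]
    all_edges = [(a, b) for a in range(n) for b in range(a + 1, n)]
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = min(best, sum(dist[a, b] for a, b in subset))
    return best


def count_sharing_pairs_bruteforce(edges):
    """Number of unordered edge pairs sharing a node, by direct enumeration."""
    edges = [tuple(e) for e in edges]
    count = 0
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            if set(edges[i]) & set(edges[j]):
                count += 1
    return count
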