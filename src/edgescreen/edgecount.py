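"""Multi-sample edge-count test on a k-MST similarity graph.

Testing whether a feature has the same conditional distribution in all J
groups is done by counting, for each group j, the number of graph edges
whose two endpoints both belong to group j:

    R_j = sum over edges (k, k') of I(y_k = y_k' = j).

Under the permutation null (group labels uniformly shuffled over the fixed
graph) the exact first two moments of R = (R_1, ..., R_J) are available in
closed form in terms of |G|, the group sizes, and the number C of edge
pairs sharing a node:

    E(R_j)   = |G| n_j (n_j - 1) / (N (N - 1))
    V(R_j)   = E(R_j)(1 - E(R_j))
               + 2C n_j(n_j-1)(n_j-2) / (N(N-1)(N-2))
               + (|G|(|G|-1) - 2C) n_j(n_j-1)(n_j-2)(n_j-3) / (N(N-1)(N-2)(N-3))
    Cov(R_j, R_j') = (|G|(|G|-1) - 2C) n_j n_j' (n_j-1)(n_j'-1)
                      / (N(N-1)(N-2)(N-3)) - E(R_j) E(R_j')

The test statistic is the quadratic form

    S = (R - E(R))^T  V(R)^{-1}  (R - E(R)),

which is asymptotically chi-square with J degrees of freedom under
regularity conditions on the graph; distributional differences inflate the
within-group counts and S.  For small groups (min n_j <= 10) a permutation
p-value on S is preferred over the asymptotic one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import pinvh
from scipy.stats import chi2

from .graph import SimilarityGraph, kmst_1d, pairwise_distances, build_kmst

__all__ = [
    "GroupLabels",
    "NullMoments",
    "EdgeCountResult",
    "count_within_group_edges",
    "null_moments",
    "edge_count_statistic",
    "permutation_pvalue",
    "edge_count_test",
]

#: largest acceptable condition number before the covariance is treated as
#: numerically singular and a symmetric pseudo-inverse is used instead
COND_LIMIT = 1e12

#: group-size threshold below which ``mode='auto'`` switches to permutation
SMALL_GROUP_SIZE = 10


@dataclass(frozen=True)
class GroupLabels:
    """Integer-coded group membership of the N pooled samples.

    ``y`` holds codes in {0, ..., J-1}; ``n`` the group sizes; ``levels``
    the original label of each code.
    """

    y: np.ndarray
    n: np.ndarray
    levels: np.ndarray

    @classmethod
    def from_array(cls, labels) -> "GroupLabels":
        labels = np.asarray(labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        levels, y = np.unique(labels, return_inverse=True)
        n = np.bincount(y, minlength=len(levels))
        return cls(y=y.astype(np.int64), n=n.astype(np.int64), levels=levels)

    @property
    def J(self) -> int:
        return len(self.n)

    @property
    def N(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class NullMoments:
    """Exact permutation-null mean vector and covariance matrix of R."""

    mean: np.ndarray
    cov: np.ndarray


@dataclass(frozen=True)
class EdgeCountResult:
    S: float
    df: int
    p_value: float
    method: str
    R: Optional[np.ndarray] = None
    n_permutations: Optional[int] = None
    degenerate: bool = False


def _as_group_labels(labels) -> GroupLabels:
    if isinstance(labels, GroupLabels):
        return labels
    return GroupLabels.from_array(labels)


def count_within_group_edges(g: SimilarityGraph, labels) -> np.ndarray:
    """R_j = number of edges with both endpoints in group j, for each j."""
    lab = _as_group_labels(labels)
    if lab.N != g.n_nodes:
        raise ValueError(
            f"label length {lab.N} does not match graph on {g.n_nodes} nodes"
        )
    yu = lab.y[g.edges[:, 0]]
    yv = lab.y[g.edges[:, 1]]
    same = yu == yv
    return np.bincount(yu[same], minlength=lab.J).astype(np.int64)


def _moments_from_graph_stats(n_edges, C, n, N):
    """Closed-form permutation moments given |G|, C and group sizes."""
    n = n.astype(float)
    G = float(n_edges)
    mean = G * n * (n - 1) / (N * (N - 1))
    pair_disjoint = G * (G - 1) - 2.0 * C
    var = (
        mean * (1.0 - mean)
        + 2.0 * C * n * (n - 1) * (n - 2) / (N * (N - 1) * (N - 2))
        + pair_disjoint
        * n * (n - 1) * (n - 2) * (n - 3)
        / (N * (N - 1) * (N - 2) * (N - 3))
    )
    cov = (
        pair_disjoint
        * np.outer(n * (n - 1), n * (n - 1))
        / (N * (N - 1) * (N - 2) * (N - 3))
        - np.outer(mean, mean)
    )
    np.fill_diagonal(cov, var)
    return mean, cov


def null_moments(g: SimilarityGraph, labels) -> NullMoments:
    """Exact mean and covariance of R under uniform label permutation."""
    lab = _as_group_labels(labels)
    if lab.N != g.n_nodes:
        raise ValueError("label length does not match graph")
    if lab.N < 4:
        raise ValueError(
            "null moments need N >= 4: the covariance formulas carry an (N-3) "
            "factor in the denominator"
        )
    deg = g.degrees.astype(float)
    C = 0.5 * float(np.sum(deg**2)) - g.n_edges
    mean, cov = _moments_from_graph_stats(g.n_edges, C, lab.n, lab.N)
    return NullMoments(mean=mean, cov=cov)


def _invert_cov(cov: np.ndarray) -> Optional[np.ndarray]:
    """Symmetric inverse with pseudo-inverse fallback; None if cov is ~0."""
    if not np.any(np.abs(cov) > 1e-14):
        return None
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[-1] <= 0:
        return None
    if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > COND_LIMIT:
        return pinvh(cov, rtol=1e-12)
    return np.linalg.inv(cov)


def edge_count_statistic(R, moments: NullMoments) -> EdgeCountResult:
    """Quadratic-form statistic S and its asymptotic chi-square p-value."""
    R = np.asarray(R, dtype=float)
    J = R.size
    if moments.mean.shape != (J,) or moments.cov.shape != (J, J):
        raise ValueError("dimension mismatch between R and null moments")
    vinv = _invert_cov(moments.cov)
    if vinv is None:
        return EdgeCountResult(
            S=0.0, df=J, p_value=1.0, method="asymptotic", R=R, degenerate=True
        )
    diff = R - moments.mean
    S = float(diff @ vinv @ diff)
    S = max(S, 0.0)
    return EdgeCountResult(
        S=S, df=J, p_value=float(chi2.sf(S, J)), method="asymptotic", R=R
    )


def _statistic_only(R, mean, vinv) -> float:
    diff = R - mean
    return max(float(diff @ vinv @ diff), 0.0)


def permutation_pvalue(
    g: SimilarityGraph, labels, B: int = 1000, seed=None
) -> EdgeCountResult:
    """Permutation p-value for S with the graph held fixed.

    Labels are permuted uniformly; p = (1 + #{S* >= S_obs}) / (B + 1), the
    add-one estimator, so the p-value is never exactly zero.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    lab = _as_group_labels(labels)
    moments = null_moments(g, lab)
    vinv = _invert_cov(moments.cov)
    R_obs = count_within_group_edges(g, lab)
    if vinv is None:
        return EdgeCountResult(
            S=0.0, df=lab.J, p_value=1.0, method="permutation", R=R_obs,
            n_permutations=B, degenerate=True,
        )
    S_obs = _statistic_only(R_obs, moments.mean, vinv)
    rng = np.random.default_rng(seed)
    u, v = g.edges[:, 0], g.edges[:, 1]
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(lab.y)
        yu, yv = perm[u], perm[v]
        same = yu == yv
        R = np.bincount(yu[same], minlength=lab.J)
        if _statistic_only(R, moments.mean, vinv) >= S_obs:
            exceed += 1
    p = (1 + exceed) / (B + 1)
    return EdgeCountResult(
        S=S_obs, df=lab.J, p_value=p, method="permutation", R=R_obs,
        n_permutations=B,
    )


def edge_count_test(
    view,
    labels,
    k: int = 3,
    mode: str = "auto",
    B: int = 1000,
    seed=None,
) -> EdgeCountResult:
    """End-to-end test of equal conditional distributions across groups.

    ``view`` is the (N,) or (N, d) sample matrix of one feature (or feature
    set); the pipeline is distances -> k-MST -> R -> null moments -> S -> p.
    ``mode='auto'`` uses the asymptotic chi-square p-value unless the
    smallest group has at most 10 samples, where the permutation p-value is
    safer.
    """
    if mode not in ("auto", "asymptotic", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    lab = _as_group_labels(labels)
    x = np.asarray(view, dtype=float)
    if x.ndim == 1:
        g = kmst_1d(x, k)
    else:
        g = build_kmst(pairwise_distances(x), k)
    if mode == "auto":
        mode = "permutation" if lab.n.min() <= SMALL_GROUP_SIZE else "asymptotic"
    if mode == "permutation":
        return permutation_pvalue(g, lab, B=B, seed=seed)
    R = count_within_group_edges(g, lab)
    return edge_count_statistic(R, null_moments(g, lab))
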