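"""Comparator tests: Welch's unequal-variance t and the mutual-information z.

Both are mean/association screens a practitioner would reach for first.
Welch's t targets location differences only; the mutual-information z-test
discretizes each feature into ~N^(1/3) equal-frequency bins, computes the
plug-in mutual information with the group label, normalizes it by the sum
of marginal entropies, and applies the Fisher-z map

    z_MI = 1/2 * log( (1 + I*) / (1 - I*) ),   I* = I_hat / (H(Y) + H(X)),

which is approximately N(0, 1/(N-3)) when feature and label are
independent.  Entropies use natural logarithms so the Fisher-z null is
internally consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "WelchResult",
    "MIResult",
    "welch_t",
    "discretize_equal_frequency",
    "mutual_information_z",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    z: float
    degenerate: bool = False


@dataclass(frozen=True)
class MIResult:
    I_hat: float
    H_y: float
    H_x: float
    I_star: float
    z_mi: float
    n_bins: int


def welch_t(x1, x0) -> WelchResult:
    """Welch's two-sample t with Welch-Satterthwaite degrees of freedom.

    t = (mean(x1) - mean(x0)) / sqrt(s1^2/n1 + s0^2/n0); the df is the
    standard Satterthwaite approximation; z is the t statistic mapped
    through its null CDF onto the normal scale.  Both groups constant is a
    degenerate case, flagged instead of raising so a screen over hundreds
    of features can skip it with a warning.
    """
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n1, n0 = x1.size, x0.size
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")
    v1 = x1.var(ddof=1)
    v0 = x0.var(ddof=1)
    if v1 == 0.0 and v0 == 0.0:
        warnings.warn("both groups have zero variance; Welch t undefined")
        return WelchResult(t=0.0, df=float(n1 + n0 - 2), z=0.0, degenerate=True)
    se2 = v1 / n1 + v0 / n0
    t = (x1.mean() - x0.mean()) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v0**2 / (n0**2 * (n0 - 1)))
    z = float(stats.norm.ppf(np.clip(stats.t.cdf(t, df), 1e-15, 1 - 1e-15)))
    return WelchResult(t=float(t), df=float(df), z=z)


def discretize_equal_frequency(x, n_bins: int) -> np.ndarray:
    """Assign equal-frequency (empirical-quantile) bin codes to ``x``.

    For distinct values the bin sizes differ by at most one; tied values
    always share a bin (they are assigned the bin of the first occurrence
    in sorted order), which can unbalance bins on heavily tied data.
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    bins = (ranks * n_bins) // n
    xs = x[order]
    # collapse ties onto the bin of their first occurrence in sorted order
    first = np.concatenate(([True], xs[1:] != xs[:-1]))
    group = np.cumsum(first) - 1
    first_bin = ((np.nonzero(first)[0]) * n_bins) // n
    bins_sorted = first_bin[group]
    out = np.empty(n, dtype=np.int64)
    out[order] = bins_sorted
    return out


def mutual_information_z(x, y, n_bins: int | None = None) -> MIResult:
    """Plug-in mutual information between a feature and group labels.

    ``x`` is discretized into ``n_bins`` equal-frequency bins (default
    ceil(N^(1/3))); entropies and MI come from the joint contingency table
    with natural logarithms.  The downstream null for z_mi is
    N(0, 1/(N-3)).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 5:
        raise ValueError("need N >= 5 (so that N^(1/3) >= 2 bins and N > 3)")
    if n_bins is None:
        n_bins = math.ceil(n ** (1.0 / 3.0))
    xb = discretize_equal_frequency(x, n_bins)
    _, yc = np.unique(y, return_inverse=True)
    n_y = int(yc.max()) + 1
    joint = np.bincount(xb * n_y + yc, minlength=n_bins * n_y).reshape(n_bins, n_y)
    pxy = joint / n

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_x = entropy(pxy.sum(axis=1))
    h_y = entropy(pxy.sum(axis=0))
    h_xy = entropy(pxy.ravel())
    i_hat = max(h_x + h_y - h_xy, 0.0)
    if h_x + h_y == 0.0:
        i_star = 0.0
    else:
        i_star = i_hat / (h_x + h_y)
    z_mi = 0.5 * math.log((1.0 + i_star) / (1.0 - i_star))
    return MIResult(I_hat=i_hat, H_y=h_y, H_x=h_x, I_star=i_star,
                    z_mi=z_mi, n_bins=int(n_bins))
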