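"""Dependence-adjusted multiple testing (Efron) and the BH comparator.

Per-feature statistics are first mapped to z-values by quantile
normalization, z_i = Phi^{-1}(F_null(stat_i)).  Correlation between tests
widens or narrows the central spread of the null z's; Efron's empirical
dispersion summary

    A = (P0 - P0_hat) / Q0,   P0 = 2 Phi(1) - 1,   P0_hat = #{|z_i| <= 1}/p

measures that departure (A ~ 0 under independence).  The rejection
threshold is then inflated through the correction factor

    A(z) = { 1 + |A| |z| phi(z) / (sqrt(2) (1 - Phi(z))) }^{-1}

and the cutoff z0 is the smallest z with

    1 - Phi(z) <= alpha * A(z) * max(1, #{z_i >= z}) / p,

scanning over the observed z-values.  With A = 0 the rule reduces exactly
to the Benjamini-Hochberg step-up on one-sided normal p-values.

Q0 = 1/sqrt(pi e) is the second-Hermite-coefficient normalizer that makes A
a proper dispersion estimate in Efron's expansion of the empirical null;
both Q0 and the sqrt(2) in A(z) are exposed as arguments so alternative
readings of the constants can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "P0",
    "Q0",
    "ZScores",
    "EfronFit",
    "SelectionResult",
    "quantile_normalize",
    "estimate_A",
    "correlation_adjustment",
    "efron_select",
    "bh_select",
]

#: central-interval mass of N(0,1): P(|Z| <= 1)
P0 = 2.0 * stats.norm.cdf(1.0) - 1.0

#: dispersion normalizer, 1/sqrt(pi*e)
Q0 = 1.0 / math.sqrt(math.pi * math.e)

#: CDF clamp applied before the normal inverse so z stays finite
CDF_EPS = 1e-15


@dataclass(frozen=True)
class ZScores:
    z: np.ndarray
    source: str = ""


@dataclass(frozen=True)
class EfronFit:
    """One dependence-adjusted selection run."""

    P0: float
    P0_hat: float
    Q0: float
    A: float
    alpha: float
    z0: float
    selected: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))


@dataclass(frozen=True)
class SelectionResult:
    selected: np.ndarray
    procedure: str

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))


def quantile_normalize(statistics, null: str, *, df=None, sigma=None,
                       source: str = "") -> ZScores:
    """Map statistics through their null CDF and the normal inverse CDF.

    ``null`` names the reference distribution:

    * ``'chi2'``  — chi-square with ``df`` degrees of freedom (edge-count S);
    * ``'t'``     — Student t with per-feature ``df`` (Welch statistics);
    * ``'normal'``— N(0, sigma^2) (the mutual-information z, sigma =
      1/sqrt(N-3)).

    CDF values are clamped to [eps, 1 - eps] before inversion so extreme
    statistics map to large finite z and still rank correctly.
    """
    s = np.asarray(statistics, dtype=float)
    if null == "chi2":
        if df is None:
            raise ValueError("chi2 null needs df")
        u = stats.chi2.cdf(s, df)
    elif null == "t":
        if df is None:
            raise ValueError("t null needs df (scalar or per-feature vector)")
        u = stats.t.cdf(s, np.asarray(df, dtype=float))
    elif null == "normal":
        if sigma is None:
            raise ValueError("normal null needs sigma")
        u = stats.norm.cdf(s, scale=sigma)
    else:
        raise ValueError(f"unknown null distribution spec {null!r}")
    u = np.clip(u, CDF_EPS, 1.0 - CDF_EPS)
    return ZScores(z=stats.norm.ppf(u), source=source)


def _z_array(z) -> np.ndarray:
    if isinstance(z, ZScores):
        z = z.z
    return np.asarray(z, dtype=float)


def estimate_A(z, p0: float = P0, q0: float = Q0) -> float:
    """Efron's dispersion summary A = (P0 - P0_hat)/Q0.

    Positive A means the central mass of z-values is thinner than the
    theoretical N(0,1) share (overdispersion, typical under positive
    correlation); A ~ 0 under independence.
    """
    zv = _z_array(z)
    if zv.size == 0:
        raise ValueError("need at least one z-value")
    p0_hat = float(np.mean(np.abs(zv) <= 1.0))
    return (p0 - p0_hat) / q0


def correlation_adjustment(z, A: float, root2: float = math.sqrt(2.0)):
    """Correction factor A(z) = 1 / (1 + |A| |z| phi(z) / (root2 (1 - Phi(z)))).

    Evaluated on the log scale (phi(z)/(1-Phi(z)) via logpdf - logsf) so the
    normal tail never underflows; always in (0, 1], and identically 1 when
    A = 0.
    """
    zv = np.asarray(z, dtype=float)
    ratio = np.abs(zv) * np.exp(stats.norm.logpdf(zv) - stats.norm.logsf(zv))
    out = 1.0 / (1.0 + abs(A) * ratio / root2)
    return out if out.ndim else float(out)


def efron_select(z, alpha: float, A: float | None = None,
                 q0: float = Q0) -> EfronFit:
    """Dependence-adjusted FDR selection at level ``alpha``.

    The cutoff scan runs over the observed z-values in decreasing order
    (the count term is piecewise constant between them); the smallest
    observed z satisfying the criterion becomes the rejection threshold and
    everything at or above it is selected.  If nothing satisfies it, z0 is
    +inf and nothing is selected.  ``A`` defaults to ``estimate_A(z)``; the
    invariant ``selected_i  <=>  z_i > z0`` holds with z0 stored as the
    supremum of the non-rejected region.
    """
    zv = _z_array(z)
    if zv.size == 0:
        raise ValueError("empty z vector")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p0_hat = float(np.mean(np.abs(zv) <= 1.0))
    if A is None:
        A = (P0 - p0_hat) / q0
    p = zv.size
    zs_desc = np.sort(zv)[::-1]
    # ties: count every z_i >= candidate, not the candidate's sort position
    counts = p - np.searchsorted(zs_desc[::-1], zs_desc, side="left")
    crit = alpha * correlation_adjustment(zs_desc, A) * counts / p
    ok = stats.norm.sf(zs_desc) <= crit
    if not ok.any():
        z0 = math.inf
        selected = np.zeros(p, dtype=bool)
    else:
        thr = zs_desc[np.nonzero(ok)[0][-1]]  # smallest satisfying z
        selected = zv >= thr
        z0 = float(np.nextafter(thr, -np.inf))
    return EfronFit(P0=P0, P0_hat=p0_hat, Q0=q0, A=float(A), alpha=alpha,
                    z0=z0, selected=selected)


def bh_select(pvalues, alpha: float) -> SelectionResult:
    """Benjamini-Hochberg step-up at level ``alpha`` (independence baseline)."""
    pv = np.asarray(pvalues, dtype=float)
    if pv.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pv < 0) | (pv > 1) | ~np.isfinite(pv)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pv, alpha=alpha, method="fdr_bh")
    return SelectionResult(selected=reject, procedure="bh")
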