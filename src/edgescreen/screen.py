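"""End-to-end feature screening: matrix in, ranked selections out.

The screen runs one of three per-feature tests (edge-count, Welch t,
mutual-information z), maps every statistic to a z-value by quantile
normalization against its null, and selects features with either Efron's
dependence-adjusted rule or Benjamini-Hochberg, both at a target FDR
``alpha``.  All multiple-testing is one-sided in z (the edge-count z is an
upper-tail transform of a chi-square statistic).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines, fdr
from .edgecount import (
    GroupLabels,
    SMALL_GROUP_SIZE,
    _invert_cov,
    _moments_from_graph_stats,
    count_within_group_edges,
    permutation_pvalue,
)
from .graph import kmst_1d, graph_diagnostics

__all__ = [
    "ExpressionMatrix",
    "ScreeningResult",
    "read_matrix",
    "normalize_expression",
    "screen_features",
    "compute_feature_zvalues",
    "write_results",
]

logger = logging.getLogger(__name__)

METHODS = ("edgecount", "welch", "mi")
PROCEDURES = ("efron", "bh")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples matrix with string identifiers.

    ``values`` is always stored features-in-rows internally regardless of
    the file orientation it was read from.
    """

    values: np.ndarray
    feature_ids: list
    sample_ids: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with id lists")
        for name, ids in (("feature", self.feature_ids),
                          ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScreeningResult:
    """Per-feature statistics plus the selection that was applied."""

    table: pd.DataFrame  # feature_id, statistic, z, p_value, selected
    method: str
    procedure: str
    alpha: float
    k: int
    mode: str
    seed: object
    threshold: float  # z0 for efron, largest rejected p for bh
    extra: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def selected_features(self) -> list:
        t = self.table
        return list(t.loc[t["selected"] == 1, "feature_id"])


def read_matrix(path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Read a TSV/CSV matrix with a header row and an id column."""
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate ids in matrix file")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "samples_in_rows":
        return ExpressionMatrix(values=values.T, feature_ids=cols, sample_ids=rows)
    return ExpressionMatrix(values=values, feature_ids=rows, sample_ids=cols)


def _trimmed_mean_sd(v: np.ndarray, trim_fraction: float):
    """Mean and sd over the values left after trimming each tail."""
    n = v.size
    cut = int(trim_fraction * n)
    core = np.sort(v)[cut:n - cut] if cut > 0 else np.sort(v)
    sd = core.std(ddof=1)
    return core.mean(), sd


def normalize_expression(m: ExpressionMatrix,
                         trim_fraction: float = 0.05) -> ExpressionMatrix:
    """Per-sample log transform followed by trimmed standardization.

    Each sample's values become (log x - trimmed mean) / trimmed sd, with
    ``trim_fraction`` (default 5%) of that sample's log-values removed from
    each tail before computing both the mean and the sd (the same trimmed
    subset is used for both).  Values must be strictly positive; data with
    zeros need an explicit offset chosen by the caller.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if np.any(m.values <= 0):
        raise ValueError(
            "normalize_expression needs strictly positive values for the log "
            "step; add an explicit pseudo-count offset first"
        )
    logged = np.log(m.values)
    out = np.empty_like(logged)
    for s in range(m.n_samples):
        mu, sd = _trimmed_mean_sd(logged[:, s], trim_fraction)
        if sd == 0:
            raise ValueError(f"sample {m.sample_ids[s]!r} has zero trimmed sd")
        out[:, s] = (logged[:, s] - mu) / sd
    return ExpressionMatrix(values=out, feature_ids=list(m.feature_ids),
                            sample_ids=list(m.sample_ids))


def _edgecount_zvalues(values, lab: GroupLabels, k: int, mode: str, B: int,
                       seed, feature_ids=None, log_diagnostics: bool = False):
    """Edge-count S, z and p for every row of a (p, N) matrix."""
    p, N = values.shape
    n = lab.n
    if mode == "auto":
        mode = "permutation" if n.min() <= SMALL_GROUP_SIZE else "asymptotic"
    S = np.empty(p)
    pvals = np.empty(p) if mode == "permutation" else None
    master = np.random.SeedSequence(seed) if seed is not None else None
    for i in range(p):
        g = kmst_1d(values[i], k)
        if log_diagnostics and i == 0 and logger.isEnabledFor(logging.INFO):
            diag = graph_diagnostics(g)
            logger.info(
                "similarity graph: |G|=%d, C=%.1f, hub term=%.1f, "
                "cluster term sum|A_e||B_e|=%.1f (o(N^1.5)=%.1f scale)",
                diag.n_edges, diag.C, diag.hub_term, diag.cluster_term,
                N ** 1.5,
            )
        if mode == "permutation":
            if master is not None:
                fid = feature_ids[i] if feature_ids is not None else str(i)
                ss = np.random.SeedSequence(
                    entropy=master.entropy,
                    spawn_key=(zlib.crc32(str(fid).encode()),),
                )
                res = permutation_pvalue(g, lab, B=B, seed=ss)
            else:
                res = permutation_pvalue(g, lab, B=B, seed=None)
            S[i] = res.S
            pvals[i] = res.p_value
        else:
            R = count_within_group_edges(g, lab)
            deg = np.bincount(g.edges.ravel(), minlength=N).astype(float)
            C = 0.5 * float(np.sum(deg**2)) - g.n_edges
            mean, cov = _moments_from_graph_stats(g.n_edges, C, n, N)
            vinv = _invert_cov(cov)
            if vinv is None:
                S[i] = 0.0
            else:
                diff = R - mean
                S[i] = max(float(diff @ vinv @ diff), 0.0)
    if mode == "permutation":
        z = stats.norm.isf(np.clip(pvals, fdr.CDF_EPS, 1 - fdr.CDF_EPS))
    else:
        pvals = stats.chi2.sf(S, lab.J)
        z = fdr.quantile_normalize(S, "chi2", df=lab.J).z
    return S, z, pvals, mode


def _welch_zvalues(values, lab: GroupLabels):
    """Vectorized Welch t, df and z across the rows of a (p, N) matrix."""
    if lab.J != 2:
        raise ValueError("Welch's t test requires exactly 2 groups")
    # group coded 1 is "x1" so that positive t means higher mean in group 1
    g1 = values[:, lab.y == 1]
    g0 = values[:, lab.y == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    v1 = g1.var(axis=1, ddof=1)
    v0 = g0.var(axis=1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    degenerate = se2 == 0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d zero-variance feature(s) skipped by Welch t", n_deg)
    t = np.zeros(values.shape[0])
    df = np.full(values.shape[0], float(n1 + n0 - 2))
    good = ~degenerate
    t[good] = (g1.mean(axis=1) - g0.mean(axis=1))[good] / np.sqrt(se2[good])
    df[good] = se2[good] ** 2 / (
        v1[good] ** 2 / (n1**2 * (n1 - 1)) + v0[good] ** 2 / (n0**2 * (n0 - 1))
    )
    z = fdr.quantile_normalize(t, "t", df=df).z
    z[degenerate] = 0.0
    return t, df, z


def _mi_zvalues(values, lab: GroupLabels):
    p, N = values.shape
    z_mi = np.empty(p)
    for i in range(p):
        z_mi[i] = baselines.mutual_information_z(values[i], lab.y).z_mi
    sigma = 1.0 / np.sqrt(N - 3)
    z = fdr.quantile_normalize(z_mi, "normal", sigma=sigma).z
    return z_mi, z


def compute_feature_zvalues(values, labels, method: str, k: int = 3,
                            mode: str = "auto", B: int = 1000, seed=None,
                            feature_ids=None, log_diagnostics: bool = False):
    """Per-feature statistic and z-value for a (p, N) matrix.

    Returns (statistic, z, p_one_sided, mode_used).  The one-sided p-value
    is 1 - Phi(z), the scale both selection procedures operate on.
    """
    lab = labels if isinstance(labels, GroupLabels) else GroupLabels.from_array(labels)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != lab.N:
        raise ValueError("values must be (n_features, n_samples) matching labels")
    if method == "edgecount":
        S, z, _, mode_used = _edgecount_zvalues(
            values, lab, k, mode, B, seed, feature_ids=feature_ids,
            log_diagnostics=log_diagnostics,
        )
        stat = S
    elif method == "welch":
        stat, _, z = _welch_zvalues(values, lab)
        mode_used = "asymptotic"
    elif method == "mi":
        stat, z = _mi_zvalues(values, lab)
        mode_used = "asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    p_one_sided = stats.norm.sf(z)
    return stat, z, p_one_sided, mode_used


def screen_features(m: ExpressionMatrix, labels, method: str = "edgecount",
                    procedure: str = "efron", alpha: float = 0.10, k: int = 3,
                    mode: str = "auto", B: int = 1000,
                    seed=None) -> ScreeningResult:
    """Run a full screen: per-feature test, then FDR selection.

    ``labels`` is a vector aligned with the matrix samples (or a
    ``GroupLabels``).  Selection is by ``procedure`` at target FDR
    ``alpha``; switching the procedure changes only the selection column,
    never the statistics or z-values.
    """
    if procedure not in PROCEDURES:
        raise ValueError(f"unknown procedure {procedure!r}")
    lab = labels if isinstance(labels, GroupLabels) else GroupLabels.from_array(labels)
    if lab.N != m.n_samples:
        raise ValueError("label length does not match number of samples")
    stat, z, p1, mode_used = compute_feature_zvalues(
        m.values, lab, method, k=k, mode=mode, B=B, seed=seed,
        feature_ids=m.feature_ids, log_diagnostics=True,
    )
    if procedure == "efron":
        fit = fdr.efron_select(z, alpha)
        selected = fit.selected
        threshold = fit.z0
        extra = {"A": fit.A, "P0_hat": fit.P0_hat}
    else:
        sel = fdr.bh_select(p1, alpha)
        selected = sel.selected
        threshold = float(p1[selected].max()) if selected.any() else 0.0
        extra = {}
    table = pd.DataFrame({
        "feature_id": m.feature_ids,
        "statistic": stat,
        "z": z,
        "p_value": p1,
        "selected": selected.astype(int),
    })
    return ScreeningResult(table=table, method=method, procedure=procedure,
                           alpha=alpha, k=k, mode=mode_used, seed=seed,
                           threshold=float(threshold), extra=extra)


def write_results(r: ScreeningResult, path) -> None:
    """Write a ranked TSV (z descending) with a commented metadata header."""
    table = r.table.sort_values("z", ascending=False, kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# method: {r.method}\n")
        fh.write(f"# procedure: {r.procedure}\n")
        fh.write(f"# alpha: {r.alpha}\n")
        fh.write(f"# k: {r.k}\n")
        fh.write(f"# mode: {r.mode}\n")
        fh.write(f"# seed: {r.seed}\n")
        fh.write(f"# threshold: {r.threshold:.10g}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
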