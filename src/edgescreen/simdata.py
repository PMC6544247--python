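"""Synthetic data with the benchmark structure used to validate the screen.

Each dataset has p = 500 continuous features over N samples and a binary
outcome.  Only the first 10 features carry signal, through four
transformation shapes

    h_i(x) = x            (features 1-3, linear)
    h_i(x) = x^3          (features 4-6, nonlinear monotone)
    h_i(x) = x^2          (features 7-8, nonlinear non-monotone)
    h_i(x) = sin(2 pi x / 3)  (features 9-10, nonlinear non-monotone)

with coefficients beta = (0.5, 0.5, -0.5, 0.5, -0.5, 0.5, 0.5, -0.5, 0.5,
-0.5).  The outcome follows either a logistic model,
Y ~ Bernoulli(expit(sum_i beta_i h_i(X_i))), or a latent-variable model,
Y = I(sum_i beta_i h_i(X_i) + eps > 0) with eps ~ N(0, 0.5^2).  Features
are either independent Unif(-1.5, 1.5) or dependent: 2 * Z with Z drawn
from N_p(0, Sigma) for a random correlation matrix Sigma with mixed-sign
entries, interval-truncated (clipped) to [-1.5, 1.5].

``run_experiment`` scores the six test x selection-procedure combinations
by empirical power (selected true signals / 10) and false discovery
proportion (false selections / max(1, selections)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fdr
from .edgecount import GroupLabels
from .screen import compute_feature_zvalues

__all__ = [
    "DEFAULT_BETAS",
    "SimulationConfig",
    "TruthSet",
    "transform_signal",
    "make_correlation_matrix",
    "generate_features",
    "generate_response",
    "generate_dataset",
    "evaluate_replication",
    "run_experiment",
]

DEFAULT_BETAS = np.array([0.5, 0.5, -0.5, 0.5, -0.5, 0.5, 0.5, -0.5, 0.5, -0.5])

MODELS = ("logistic", "latent")
DEPENDENCIES = ("independent", "dependent")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the benchmark grid.

    Defaults reproduce the benchmark conditions: p = 500 features, 10
    signals with the betas above, target FDR alpha = 0.10, 3-MST similarity
    graph, latent-model noise sd 0.5, dependent features scaled by 2 and
    clipped at +/- 1.5.
    """

    model: str = "logistic"
    dependency: str = "independent"
    N: int = 200
    p: int = 500
    betas: np.ndarray = field(default_factory=lambda: DEFAULT_BETAS.copy())
    noise_sd: float = 0.5
    scale_factor: float = 2.0
    truncation: float = 1.5
    truncation_mode: str = "clip"  # or "resample"
    k: int = 3
    alpha: float = 0.10
    replications: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.dependency not in DEPENDENCIES:
            raise ValueError(f"dependency must be one of {DEPENDENCIES}")
        object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))
        if len(self.betas) != 10:
            raise ValueError("betas must have length 10")


@dataclass(frozen=True)
class TruthSet:
    """Indices (0-based) of the features truly associated with the outcome."""

    signal_indices: frozenset = frozenset(range(10))


def transform_signal(x, i: int):
    """Signal transformation h_i for 1-based feature index i in 1..10."""
    if not 1 <= i <= 10:
        raise ValueError("signal feature index must be in 1..10")
    x = np.asarray(x, dtype=float)
    if i <= 3:
        out = x
    elif i <= 6:
        out = x**3
    elif i <= 8:
        out = x**2
    else:
        out = np.sin(2.0 * np.pi * x / 3.0)
    return out if out.ndim else float(out)


def make_correlation_matrix(p: int, seed=None) -> np.ndarray:
    """Random correlation matrix with mixed-sign entries (C-vine sampler).

    Partial correlations are drawn symmetrically around zero via shifted
    Beta draws (the vine construction with uniform shape, giving a diffuse
    distribution over correlation matrices), then composed into full
    correlations; the result is symmetric positive-definite with unit
    diagonal and both positive and negative off-diagonals.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    rng = np.random.default_rng(seed)
    P = np.zeros((p, p))
    S = np.eye(p)
    beta_shape = 1.0 + (p - 1) / 2.0
    for kk in range(p - 1):
        shape = beta_shape - kk / 2.0
        vals = rng.beta(shape, shape, size=p - kk - 1) * 2.0 - 1.0
        P[kk, kk + 1:] = vals
        pc = vals.copy()
        for ll in range(kk - 1, -1, -1):
            pc = pc * np.sqrt(
                (1.0 - P[ll, kk + 1:] ** 2) * (1.0 - P[ll, kk] ** 2)
            ) + P[ll, kk + 1:] * P[ll, kk]
        S[kk, kk + 1:] = pc
        S[kk + 1:, kk] = pc
    return S


def generate_features(cfg: SimulationConfig, rng=None,
                      sigma_chol: np.ndarray | None = None) -> np.ndarray:
    """N x p feature matrix under the configured dependency structure.

    ``sigma_chol`` (a Cholesky factor of the correlation matrix) can be
    passed in so the same Sigma is reused across replications; it is drawn
    fresh from ``rng`` when absent and the dependency is 'dependent'.
    """
    rng = np.random.default_rng(rng)
    if cfg.dependency == "independent":
        return rng.uniform(-cfg.truncation, cfg.truncation, size=(cfg.N, cfg.p))
    if sigma_chol is None:
        sigma = make_correlation_matrix(cfg.p, rng)
        sigma_chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((cfg.N, cfg.p)) @ sigma_chol.T
    x = cfg.scale_factor * z
    if cfg.truncation_mode == "clip":
        return np.clip(x, -cfg.truncation, cfg.truncation)
    # resample mode: redraw out-of-range entries from within the interval
    bad = np.abs(x) > cfg.truncation
    while bad.any():
        z_new = rng.standard_normal(int(bad.sum()))
        x[bad] = cfg.scale_factor * z_new
        bad = np.abs(x) > cfg.truncation
    return x


def generate_response(X: np.ndarray, cfg: SimulationConfig, rng=None) -> np.ndarray:
    """Binary outcome from the configured model on signal features 1-10."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 10:
        raise ValueError("feature matrix must have at least 10 columns")
    rng = np.random.default_rng(rng)
    score = np.zeros(X.shape[0])
    for i in range(10):
        score += cfg.betas[i] * transform_signal(X[:, i], i + 1)
    if cfg.model == "logistic":
        prob = 1.0 / (1.0 + np.exp(-score))
        return (rng.random(X.shape[0]) < prob).astype(np.int64)
    noise = rng.normal(0.0, cfg.noise_sd, size=X.shape[0])
    return (score + noise > 0).astype(np.int64)


def generate_dataset(cfg: SimulationConfig, rng=None,
                     sigma_chol: np.ndarray | None = None):
    """Convenience: one (X, y) draw under ``cfg``."""
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    X = generate_features(cfg, rng, sigma_chol=sigma_chol)
    y = generate_response(X, cfg, rng)
    return X, y


def evaluate_replication(selected, truth: TruthSet | None = None):
    """(fdp, power) of one selection against the known signal set."""
    truth = truth or TruthSet()
    selected = np.asarray(selected).astype(bool)
    sel_idx = set(np.nonzero(selected)[0].tolist())
    true_idx = set(truth.signal_indices)
    n_true_pos = len(sel_idx & true_idx)
    n_false_pos = len(sel_idx - true_idx)
    fdp = n_false_pos / max(1, len(sel_idx))
    power = n_true_pos / len(true_idx)
    return fdp, power


def _replication_selections(X, y, cfg, methods, procedures):
    """Selections of every requested method x procedure pair on one draw."""
    lab = GroupLabels.from_array(y)
    out = {}
    for method in methods:
        _, z, p1, _ = compute_feature_zvalues(X.T, lab, method, k=cfg.k)
        for procedure in procedures:
            if procedure == "efron":
                sel = fdr.efron_select(z, cfg.alpha).selected
            else:
                sel = fdr.bh_select(p1, cfg.alpha).selected
            out[(method, procedure)] = sel
    return out


def run_experiment(configs, methods=("edgecount", "welch", "mi"),
                   procedures=("efron", "bh"), seed=None,
                   progress: bool = False) -> pd.DataFrame:
    """Power / FDP table over a grid of simulation settings.

    ``configs`` is an iterable of ``SimulationConfig``; each is replicated
    ``cfg.replications`` times with per-replication seeds derived from
    ``seed`` (or ``cfg.seed``), a fixed correlation matrix per setting, and
    every method x procedure pair scored on the same draws.  Returns a
    tidy DataFrame keyed by (method, procedure, model, dependency, N) with
    mean power, mean FDP and their Monte-Carlo standard errors.
    """
    rows = []
    for cfg in configs:
        master = np.random.SeedSequence(
            seed if seed is not None else (cfg.seed or 0)
        )
        sigma_ss, reps_ss = master.spawn(2)
        sigma_chol = None
        if cfg.dependency == "dependent":
            sigma = make_correlation_matrix(cfg.p, np.random.default_rng(sigma_ss))
            sigma_chol = np.linalg.cholesky(sigma)
        rep_seeds = reps_ss.spawn(cfg.replications)
        scores = {(m, pr): {"fdp": [], "power": []}
                  for m in methods for pr in procedures}
        for r in range(cfg.replications):
            rng = np.random.default_rng(rep_seeds[r])
            X = generate_features(cfg, rng, sigma_chol=sigma_chol)
            y = generate_response(X, cfg, rng)
            if len(np.unique(y)) < 2:  # all-one-class draw carries no test
                continue
            sels = _replication_selections(X, y, cfg, methods, procedures)
            for key, sel in sels.items():
                f, pw = evaluate_replication(sel)
                scores[key]["fdp"].append(f)
                scores[key]["power"].append(pw)
            if progress and (r + 1) % 10 == 0:
                print(f"  {cfg.model}/{cfg.dependency} N={cfg.N}: "
                      f"{r + 1}/{cfg.replications} replications", flush=True)
        for (m, pr), vals in scores.items():
            f = np.asarray(vals["fdp"])
            pw = np.asarray(vals["power"])
            nrep = len(f)
            rows.append({
                "method": m, "procedure": pr, "model": cfg.model,
                "dependency": cfg.dependency, "N": cfg.N,
                "power": pw.mean() if nrep else math.nan,
                "fdp": f.mean() if nrep else math.nan,
                "power_se": pw.std(ddof=1) / math.sqrt(nrep) if nrep > 1 else math.nan,
                "fdp_se": f.std(ddof=1) / math.sqrt(nrep) if nrep > 1 else math.nan,
                "replications": nrep,
            })
    return pd.DataFrame(rows)


def setting_grid(Ns=(50, 100, 200, 500), models=MODELS,
                 dependencies=DEPENDENCIES, **kwargs):
    """All model x dependency x N combinations as SimulationConfigs."""
    return [
        SimulationConfig(model=m, dependency=d, N=n, **kwargs)
        for m, d, n in itertools.product(models, dependencies, Ns)
    ]
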