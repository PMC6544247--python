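# edgescreen

Model-free screening of continuous features against a categorical outcome
— for example, selecting genes whose expression distribution differs
between phenotype groups — built for settings where effects are nonlinear
and features are correlated, so that mean-based tests and
independence-assuming FDR procedures both break down.

The screen has two steps:

1. **Edge-count test per feature.** A k-MST similarity graph (union of k
   edge-disjoint minimum spanning trees, Euclidean distance, default
   k = 3) is built on the pooled samples. For each group j the number of
   within-group edges R_j = Σ_{(a,b)∈G} I(y_a = y_b = j) is compared with
   its exact permutation-null moments through the quadratic form
   S = (R − E R)ᵀ V(R)⁻¹ (R − E R), which is asymptotically χ²_J. Because
   S targets the full conditional distribution rather than the mean, it
   reacts to variance, multimodality and other shape differences that a
   t-test cannot see. Small groups (min nⱼ ≤ 10) automatically switch to a
   permutation p-value.
2. **Dependence-adjusted FDR selection.** Statistics are
   quantile-normalized to z-values; Efron's empirical-null dispersion
   A = (P₀ − P̂₀)/Q₀ (P₀ = 2Φ(1)−1, Q₀ = 1/√(πe)) measures how correlation
   distorts the central z mass, and the rejection cutoff z₀ is the
   smallest z with 1 − Φ(z) ≤ α·A(z)·max(1, #{zᵢ ≥ z})/p, where
   A(z) = {1 + |A||z|φ(z)/(√2(1−Φ(z)))}⁻¹. With A = 0 this is exactly
   Benjamini–Hochberg on one-sided normal p-values.

Welch's unequal-variance t (with Welch–Satterthwaite df) and a
mutual-information z-test (equal-frequency binning, Fisher-z of normalized
MI) are included as comparators, and `simdata` reproduces a full
simulation benchmark (logistic / latent-variable outcomes, independent /
correlated features, 10 nonlinear signal features among p = 500).

## Worked example

```python
import numpy as np
from edgescreen import edge_count_test, welch_t

rng = np.random.default_rng(7)
x = np.concatenate([
    rng.normal(0.0, 1.0, 60),                                   # unimodal
    rng.choice([-1.0, 1.0], 60) + rng.normal(0.0, 0.25, 60),    # bimodal
])
y = np.repeat([0, 1], 60)

res = edge_count_test(x, y, k=3)
w = welch_t(x[y == 1], x[y == 0])
print(res.S, res.p_value)   # 51.45  6.74e-12
print(w.t, w.df)            # 0.988  116.1
```

The two groups have equal means, so Welch's t (0.99, n.s.) sees nothing;
the within-group edge counts R = (117, 125) sit far above their null
expectation (88.5 each for a 3-MST with 357 edges), giving S = 51.5 on 2 df
and p ≈ 7e-12. The scripts in `examples/` extend this to a full matrix
screen (`screen_matrix.py`, which prints the ranked selection table) and a
power/FDP study across methods (`power_study.py`).

A matrix screen from the shell:

```sh
edgescreen run --matrix expr.tsv --labels groups.tsv \
    --method edgecount --mt efron --alpha 0.10 --kmst 3 \
    --normalize --seed 7 --out results.tsv
edgescreen simulate --model logistic --dependency independent \
    --N 200 --p 500 --reps 100 --seed 11 --out table.tsv
```

`--normalize` applies the per-sample log + 5%-trimmed standardization used
for positive-valued expression matrices; the labels file is a two-column
TSV (sample_id, group).

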