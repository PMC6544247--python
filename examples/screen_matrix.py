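"""Screen a small expression matrix for group-associated features.

Builds a synthetic 80-gene x 60-sample matrix in which five genes differ
between the two phenotype groups (two by location, three by shape only),
runs the edge-count screen with Efron's dependence-adjusted selection, and
prints the ranked hits.
"""

import numpy as np

from edgescreen import ExpressionMatrix, screen_features

rng = np.random.default_rng(11)
p, n = 80, 60
y = np.repeat([0, 1], n // 2)

values = rng.normal(size=(p, n))
values[0:2, y == 1] += 2.0                      # location effects
for i in (2, 3, 4):                              # shape effects, equal means
    values[i, y == 1] = rng.choice([-1.3, 1.3], n // 2) + rng.normal(0, 0.3, n // 2)

m = ExpressionMatrix(values=values,
                     feature_ids=[f"gene{i:02d}" for i in range(p)],
                     sample_ids=[f"s{j:02d}" for j in range(n)])

res = screen_features(m, y, method="edgecount", procedure="efron",
                      alpha=0.10, k=3, seed=1)

print(f"selected {res.n_selected} of {p} features at target FDR "
      f"{res.alpha} (threshold z0 = {res.threshold:.3f}, "
      f"dispersion A = {res.extra['A']:.3f})")
print()
print(res.table.sort_values("z", ascending=False).head(8).to_string(index=False))
print()
print("Genes 00-04 carry the planted effects; their statistics S and")
print("z-values rank far above the 75 null genes, and the selection column")
print("marks everything past Efron's dependence-adjusted cutoff z0.")
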