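"""Score the six test x selection-procedure combinations on synthetic data.

Runs a reduced version of the benchmark simulation (smaller p and few
replications so it finishes in seconds): a binary outcome generated from
ten signal features through linear, cubic, quadratic and sinusoidal
transformations, screened by the edge-count, Welch-t and MI-z tests under
Efron and BH selection.  Power is the fraction of the ten signal features
selected; FDP the fraction of selections that are not signals.
"""

from edgescreen import SimulationConfig, run_experiment

cfgs = [
    SimulationConfig(model="latent", dependency="independent",
                     N=200, p=100, replications=10),
]
table = run_experiment(cfgs, seed=3)

print(table[["method", "procedure", "power", "fdp", "power_se"]]
      .to_string(index=False, float_format="%.3f"))
print()
print("Each row averages 10 replications of the latent-variable design at")
print("N=200: 'power' is the mean fraction of the 10 planted signals the")
print("procedure recovered, 'fdp' the mean false-discovery proportion at")
print("target FDR 0.10. The additive ten-feature design dilutes per-feature")
print("distributional differences, which favors the mean-based Welch test;")
print("see docs/methods.md for the full analysis.")
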