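"""Wild type: a Fj gradient polarizes every cell's Ft-Ds heterodimer distally.

Builds the default 20-cell row (linear Fj gradient up, linear total-Ds
gradient down, uniform total Ft), integrates the phosphorylation kinetics
to steady state from a random initial condition, and prints each interior
cell's heterodimer asymmetry delta_c = C(distal edge) - C(proximal edge).
Positive delta_c means distal enrichment — the cellular precursor of the
distal-pointing wing hair.
"""

import numpy as np

from fatds import PerturbationSpec, SimulationConfig, run_experiment

config = SimulationConfig.default()
result = run_experiment(PerturbationSpec("wild_type"), config, seed=1)

print(f"converged: {result.converged} (t = {result.convergence_time:g})")
print("cell  delta_c   label")
for cell, dc, label in zip(
    range(2, config.profiles.n_cells),
    result.polarity.delta_c,
    result.polarity.labels,
):
    print(f"{cell:4d}  {dc:+.5f}  {label}")

grad = np.diff(result.edges.c_total)
print(f"\nedge heterodimer C rises monotonically proximal->distal: {np.all(grad > 0)}")
print(f"C ranges from {result.edges.c_total[0]:.3f} (proximal-most edge) "
      f"to {result.edges.c_total[-1]:.3f} (distal-most edge)")
print("\nEvery interior cell has delta_c > 0: the heterodimer is enriched on its")
print("distal edge, and the tissue also shows a distally rising edge gradient.")
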