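"""Weighting the two polarity mechanisms: Ds-polarity amplifies asymmetry.

The steady-state asymmetry decomposes as
delta_c = (k_on/k_off) * (p_ft + mu * p_ds), where p_ft is the cell's own
phosphorylated-Ft polarity and p_ds its unphosphorylated-Ds polarity. A
single wild-type steady state is re-weighted at mu = 0.1, 1 and 10.
"""

import numpy as np

from fatds import SimulationConfig, mu_sweep

config = SimulationConfig.default()
table = mu_sweep([0.1, 1.0, 10.0], config, seed=1)

for mu, sub in table.groupby("mu"):
    sub = sub.sort_values("cell_index")
    dc = sub.delta_c.to_numpy()
    print(
        f"mu = {mu:>4}: delta_c in [{dc.min():+.4f}, {dc.max():+.4f}], "
        f"{(sub.label == 'distal').sum()} distal / "
        f"{(sub.label == 'proximal').sum()} proximal cells"
    )

dc01 = table[table.mu == 0.1].sort_values("cell_index").delta_c.to_numpy()
first_reversed = 2 + int(np.argmax(dc01 < 0))
print(f"\nAt mu = 0.1 polarity is reversed from cell {first_reversed} distalward, while")
print("the proximal-most interior cells stay (weakly) distal. Raising mu to 10")
print("amplifies every cell's distal asymmetry ~10-fold: the unphosphorylated-Ds")
print("polarity term is what drives distal enrichment.")
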