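# Methods

## Model and assumptions

The package models a single proximo-distal row of wing epithelial cells.
Per cell *i* it tracks phosphorylated Fat (Ftᵖ) and phosphorylated Dachsous
(Dsᵖ); everything else is algebraic. The assumptions, in order of
importance:

- **Fixed totals.** Total Ft and total Ds per cell are constant during
  polarization; unphosphorylated pools follow by conservation. Total Ft is
  uniform across the row; total Ds falls linearly proximal→distal.
- **Fj activity ≡ Fj expression.** The kinase activity gradient is taken
  to be synonymous with the expression gradient: the model consumes a
  single per-cell `fj` vector and feeds it through a Hill function
  H(fj) = fjⁿ/(Kⁿ + fjⁿ). There is no separate expression/activity layer.
- **Cell-autonomous phosphorylation.** Phosphorylation happens in each
  cell's Golgi, driven by its own Fj only; the phosphorylation ODEs are
  linear and uncoupled between cells.
- **One dimer species.** Fj phosphorylation raises Ft's affinity for Ds
  and lowers Ds's affinity for Ft, so only the Ftᵖ–Dsᵘ pair binds. The
  three weaker pairings (Ftᵘ–Dsᵘ, Ftᵖ–Dsᵖ, Ftᵘ–Dsᵖ) are dropped.
- **No monomer feedback.** Heterodimer formation at the edges does not
  deplete the monomer pools (binding and phosphorylation occur in
  different compartments). Edge concentrations are therefore slaved linear
  relaxations toward (k_on/k_off) × (binding flux).
- **1-D tissue.** Each cell has exactly one proximal and one distal
  neighbor; the two tissue-boundary faces carry no dimer, so asymmetry is
  defined only for interior cells. Core PCP proteins (Fz/Vang/Pk/Dsh) and
  2-D effects are out of scope.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `n_cells` | cells in the row | 20 | ≥3 so at least one interior cell exists |
| `alpha_ft`, `alpha_ds` | phosphorylation rates (1/time) | 2 | symmetric between substrates by default |
| `beta_ft`, `beta_ds` | dephosphorylation rates (1/time) | 0.1 | must be >0 for steady states to exist |
| `hill_n` | Hill coefficient | 1 | shared by both substrates; `hill_n_ds`/`hill_k_ds` override per-substrate |
| `hill_k` | Hill half-saturation | 250 | with fj ∈ (0, 1], H is in its near-linear regime (H ≈ fj/250) |
| `k_on`, `k_off` | dimer association/dissociation | 1, 0.1 | only their ratio enters steady states |
| `mu` | weight on the Dsᵘ-polarity term | 1 | μ=1 makes ΔC the literal edge difference |

Units are normalized: Ft levels by total Ft per cell; Ds and Fj levels by
their totals in the distal-most cell.

### Wild-type profiles

The gradients are specified in the literature by shape, not magnitude. The
package's defaults:

- `fj[i] = i/N` (1-based): linear, strictly positive everywhere, exactly 1
  in the distal-most cell. The alternative (i−1)/(N−1) convention would
  zero Fj in the proximal-most cell; either satisfies the qualitative
  description, and the choice only shifts the proximal boundary cell.
- `ds_total[i] = 1 + s·(N−i)/N` with slope `s = 0.5`: falls to exactly 1
  distally. The slope is a genuine free choice; s = 0.5 is the default
  because it produces the full reference phenotype set — every interior
  cell distal in wild type *and* a μ=0.1 reversal confined to the distal
  cells — whereas s = 1 tips the distal-most interior cell marginally
  proximal in wild type. Both endpoints are configurable
  (`profiles.ds_proximal` etc. in the config file).
- `ft_total = 1` everywhere.

## Numerics

- **Integrator.** Explicit forward Euler, the model's native
  discretization, with `dt = 0.1`, `t_max = 500`, convergence tolerance
  `tol = 1e-8` on the max absolute rate. All equations are linear
  relaxations, so the stability limit is `2/max(rate)`;
  `stability_bound()` computes it (≈18.5 at defaults) and the integrator
  refuses larger steps. Relaxation rates are ≥ β = 0.1, so t_max = 500 is
  ≥50 relaxation times. A closed-form solution of the linear ODEs
  (`analytic_relaxation`, `steady_state_phospho`) serves as the exact
  oracle in tests; it is never the production integration path.
- **Accuracy.** The scheme is first order: the measured max deviation from
  the exact trajectory at defaults is ≈2.5e-3 (dt = 0.1) and halves with
  dt; the converged state matches the exact fixed point to ≈1e-7 when
  stopping at tol = 1e-8.
- **Experiments integrate the full window.** `run_experiment` disables
  early stopping: after 500 time units the slowest mode has decayed by
  e⁻⁵⁰, so the reported state sits at the floating-point fixed point
  (residual ~1e-16). This makes near-zero asymmetries (flattened-gradient
  and kinase-dead tissues) classifiable and the outcome exactly
  seed-independent, which an early stop at rate < 1e-8 (state residual
  ~1e-7, different for every seed) would not. Early stopping remains the
  default for direct `integrate_phospho` use.
- **Classification tolerance.** `classify_polarity` labels a cell distal
  (proximal) when ΔC > tol (< −tol), default `tol = 1e-12` in normalized
  concentration units: comfortably above the ~1e-16 fixed-point residual,
  and below the asymmetry of every genuinely polarized regime exercised —
  including steep Hill coefficients (n = 4 with K = 250 scales all
  concentrations down by ~(fj/K)³, leaving proximal-cell ΔC near 3e-10 but
  still strictly positive). An absolute threshold much larger than this
  would misread such uniformly scaled-down tissues as unpolarized.
- **Trajectory storage** is thinned (every 10th step by default) to bound
  memory; convergence checks always use the unthinned current state. Edge
  integration reads the (thinned) phospho trajectory by linear
  interpolation.
- **Degenerate inputs.** fj = 0 gives H = 0 exactly; α = 0 (kinase-dead)
  gives a pure-decay channel with steady state 0; uniform profiles give
  exactly zero polarity terms, so flatten-both tissues report ΔC = 0 to
  machine precision.

## Orientation and sign conventions

Edge *j* joins cells *j* and *j+1*. Its dimer splits into
`c_orient_ds_distal` (proximal-side cell's Dsᵘ bound to distal-side cell's
Ftᵖ — the orientation favored at steady state in wild type) and
`c_orient_ft_distal` (the converse); they sum exactly to `c_total`. The
weight μ multiplies the Dsᵘ-polarity term P_Ds: μ = 10 corresponds to a
dominant Dsᵘ contribution (amplified distal asymmetry), μ = 0.1 to a
dominant Ftᵖ contribution (diminished or reversed asymmetry in distal
cells). This convention is fixed by the sign structure at the wild-type
steady state (P_Ds > 0, P_Ft < 0); the reciprocal convention would be a
weight on P_Ft and is not exposed.

## What the synthetic tissue does and does not emulate

The generator reproduces the study conditions: smooth linear opposing
gradients, uniform total Ft, and uncorrelated uniform-random initial
phosphorylation per cell. It does **not** model cell-to-cell expression
noise, cell geometry or packing disorder, stochastic reaction kinetics,
mosaic (clonal) perturbations, or feedback from dimer formation onto
expression. Passing tests therefore demonstrate the deterministic
steady-state logic of the gradient-readout mechanism, not its robustness
to biological noise or 2-D tissue topology.

## Known limitations

- Strictly 1-D; no notion of polarity direction other than ±along the row.
- The heterodimer is slaved to the phospho state; phenomena requiring
  dimer-monomer feedback (e.g. mutual inhibition between the two edge
  orientations) are outside the model class.
- Uniform-overexpression levels for the flatten experiments default to the
  wild-type profile maximum; the qualitative outcome is level-independent
  (the Ds-polarity term vanishes identically once Fj is uniform), so the
  level is presentational.
- The forward-Euler path trades accuracy for fidelity to the model's
  difference-scheme formulation; users needing tighter trajectories should
  reduce `dt` (error is linear in it) rather than extend `t_max`.
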