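"""In-silico genetics: wild type, gradient flattening, kinase-dead mutants, sweeps.

Each experiment builds the wild-type tissue, applies a tissue-wide
perturbation, integrates the phosphorylation dynamics to steady state from
a seeded random initial condition, and classifies each interior cell's
heterodimer asymmetry as distal, proximal, or unpolarized.

Perturbation kinds
------------------
- ``wild_type``: no change.
- ``flatten_fj`` / ``flatten_ds`` / ``flatten_both``: uniform
  overexpression — the profile is set flat at ``flatten_level`` (default:
  the wild-type profile maximum).
- ``fj_ft_dead`` / ``fj_ds_dead``: the kinase retains activity against one
  substrate only; the other phosphorylation rate is set to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import check_steady, integrate_phospho
from .heterodimer import (
    CLASSIFY_TOL,
    EdgeState,
    PolarityResult,
    edge_steady_state,
    polarity_result,
    weighted_asymmetry,
)
from .model_core import ExpressionProfiles, ModelParameters, PhosphoState
from .synthetic_data import default_wildtype_config, random_initial_state, uniform_profile

__all__ = [
    "PERTURBATION_KINDS",
    "PerturbationSpec",
    "SimulationConfig",
    "ExperimentResult",
    "apply_perturbation",
    "run_experiment",
    "mu_sweep",
    "sensitivity_sweep",
]

PERTURBATION_KINDS = (
    "wild_type",
    "flatten_fj",
    "flatten_ds",
    "flatten_both",
    "fj_ft_dead",
    "fj_ds_dead",
)

#: names accepted by sensitivity_sweep; "rate_scale" multiplies all four
#: phosphorylation rate constants jointly (the steady state is invariant
#: under that scaling, only the relaxation speed changes)
_SWEEPABLE = ("alpha_ft", "beta_ft", "alpha_ds", "beta_ds", "hill_n", "hill_k",
              "k_on", "k_off", "mu", "rate_scale")


@dataclass(frozen=True)
class PerturbationSpec:
    """A tissue-wide perturbation to apply before simulating."""

    kind: str = "wild_type"
    flatten_level: float | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(
                f"unknown perturbation kind {self.kind!r}; expected one of {PERTURBATION_KINDS}"
            )
        if self.flatten_level is not None:
            if not self.kind.startswith("flatten"):
                raise ValueError("flatten_level is only meaningful for flatten kinds")
            if self.flatten_level <= 0:
                raise ValueError("flatten_level must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one experiment: model, tissue, integration."""

    params: ModelParameters
    profiles: ExpressionProfiles
    dt: float = 0.1
    t_max: float = 500.0
    tol: float = 1e-8
    classify_tol: float = CLASSIFY_TOL

    @classmethod
    def default(cls) -> "SimulationConfig":
        params, profiles = default_wildtype_config()
        return cls(params=params, profiles=profiles)


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one experiment run."""

    spec: PerturbationSpec
    params: ModelParameters
    profiles: ExpressionProfiles
    final_state: PhosphoState
    edges: EdgeState
    polarity: PolarityResult
    converged: bool
    convergence_time: float | None
    seed: int


def apply_perturbation(
    profiles: ExpressionProfiles,
    params: ModelParameters,
    spec: PerturbationSpec,
) -> tuple[ExpressionProfiles, ModelParameters]:
    """Return perturbed copies of the profiles and parameters (inputs untouched)."""
    n = profiles.n_cells
    fj, ds_total = profiles.fj, profiles.ds_total
    kind = spec.kind
    if kind in ("flatten_fj", "flatten_both"):
        level = spec.flatten_level if spec.flatten_level is not None else float(fj.max())
        fj = uniform_profile(n, level)
    if kind in ("flatten_ds", "flatten_both"):
        level = (
            spec.flatten_level if spec.flatten_level is not None else float(ds_total.max())
        )
        ds_total = uniform_profile(n, level)
    new_profiles = ExpressionProfiles(fj=fj, ds_total=ds_total, ft_total=profiles.ft_total)

    new_params = params
    if kind == "fj_ft_dead":
        new_params = replace(new_params, alpha_ft=0.0)
    elif kind == "fj_ds_dead":
        new_params = replace(new_params, alpha_ds=0.0)
    if spec.overrides:
        new_params = replace(new_params, **spec.overrides)
    return new_profiles, new_params


def run_experiment(
    spec: PerturbationSpec,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Run one perturbation experiment to steady state and classify polarity.

    The integration runs the full time window (rather than stopping at the
    convergence tolerance) so that the reported state sits at the numerical
    fixed point; classification then reflects the model's steady state and
    not the integrator's stopping residual. Convergence is still checked
    and reported. Deterministic given (config, seed).
    """
    if config is None:
        config = SimulationConfig.default()
    profiles, params = apply_perturbation(config.profiles, config.params, spec)
    initial = random_initial_state(profiles, seed)
    traj = integrate_phospho(
        initial,
        profiles,
        params,
        dt=config.dt,
        t_max=config.t_max,
        tol=config.tol,
        early_stop=False,
    )
    converged, idx = check_steady(traj, config.tol)
    convergence_time = float(traj.times[idx]) if converged else None
    final = traj.final_state
    edges = edge_steady_state(final, profiles, params)
    polarity = polarity_result(final, profiles, params, tol=config.classify_tol)
    return ExperimentResult(
        spec=spec,
        params=params,
        profiles=profiles,
        final_state=final,
        edges=edges,
        polarity=polarity,
        converged=converged,
        convergence_time=convergence_time,
        seed=seed,
    )


def mu_sweep(
    mu_values,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-evaluate the weighted asymmetry of one wild-type steady state per mu.

    The phosphorylation dynamics do not involve mu, so a single steady
    state serves all weights. Returns a tidy table with one row per
    (mu, interior cell), ordered by mu then cell.
    """
    mu_values = [float(m) for m in mu_values]
    if any(m < 0 for m in mu_values):
        raise ValueError("all mu values must be >= 0")
    if config is None:
        config = SimulationConfig.default()
    result = run_experiment(PerturbationSpec("wild_type"), config, seed)
    from .heterodimer import classify_polarity

    rows = []
    interior = np.arange(2, config.profiles.n_cells)  # 1-based interior cell indices
    for mu in sorted(mu_values):
        delta_c = weighted_asymmetry(result.final_state, result.profiles, result.params, mu=mu)
        labels = classify_polarity(delta_c, config.classify_tol)
        for cell, dc, lab in zip(interior, delta_c, labels):
            rows.append({"mu": mu, "cell_index": int(cell), "delta_c": float(dc), "label": lab})
    return pd.DataFrame(rows, columns=["mu", "cell_index", "delta_c", "label"])


def _apply_point(params: ModelParameters, point: dict) -> ModelParameters:
    out = params
    for name, value in point.items():
        if name == "rate_scale":
            out = replace(
                out,
                alpha_ft=out.alpha_ft * value,
                beta_ft=out.beta_ft * value,
                alpha_ds=out.alpha_ds * value,
                beta_ds=out.beta_ds * value,
            )
        else:
            out = replace(out, **{name: value})
    return out


def sensitivity_sweep(
    param_grid: dict,
    config: SimulationConfig | None = None,
    seed: int = 0,
    mode: str = "one_at_a_time",
) -> pd.DataFrame:
    """Fraction of interior cells classified distal across a parameter sweep.

    ``mode="one_at_a_time"`` varies each listed parameter alone with the
    others at their configured values (rows: parameter, value,
    fraction_distal); ``mode="cartesian"`` runs the full product grid (one
    column per parameter). The special name ``rate_scale`` multiplies all
    four phosphorylation rate constants jointly. Each point re-runs the
    wild-type experiment.
    """
    if mode not in ("one_at_a_time", "cartesian"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if config is None:
        config = SimulationConfig.default()
    for name in param_grid:
        if name not in _SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {name!r}; expected one of {_SWEEPABLE}")

    def fraction_distal(point: dict) -> float:
        cfg = replace(config, params=_apply_point(config.params, point))
        res = run_experiment(PerturbationSpec("wild_type"), cfg, seed)
        return float(np.mean(res.polarity.labels == "distal"))

    if not param_grid:
        return pd.DataFrame(
            [{"parameter": "default", "value": np.nan, "fraction_distal": fraction_distal({})}]
        )

    if mode == "one_at_a_time":
        rows = []
        for name in sorted(param_grid):
            for value in sorted(float(v) for v in param_grid[name]):
                rows.append(
                    {
                        "parameter": name,
                        "value": value,
                        "fraction_distal": fraction_distal({name: value}),
                    }
                )
        return pd.DataFrame(rows, columns=["parameter", "value", "fraction_distal"])

    names = sorted(param_grid)
    rows = []
    for combo in itertools.product(*(sorted(float(v) for v in param_grid[n]) for n in names)):
        point = dict(zip(names, combo))
        row = dict(point)
        row["fraction_distal"] = fraction_distal(point)
        rows.append(row)
    return pd.DataFrame(rows, columns=[*names, "fraction_distal"])
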