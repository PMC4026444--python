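"""Configuration files, result serialization, and the trapezoid-plot export.

Config files are a flat YAML subset: scalar keys, optionally grouped one
level deep under ``model``, ``profiles``, ``integration`` or ``experiment``.
Missing keys fall back to the wild-type defaults; unknown keys are errors
(no silently ignored typos). Results are written as TSV (locale-proof
decimals) plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .experiments import (
    PERTURBATION_KINDS,
    ExperimentResult,
    PerturbationSpec,
    SimulationConfig,
)
from .heterodimer import CLASSIFY_TOL
from .model_core import ModelParameters
from .synthetic_data import wildtype_profiles

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "write_config",
    "write_results",
    "export_trapezoid_plot",
]

_MODEL_KEYS = (
    "n_cells", "alpha_ft", "beta_ft", "alpha_ds", "beta_ds",
    "hill_n", "hill_k", "k_on", "k_off", "mu", "hill_n_ds", "hill_k_ds",
)
_PROFILE_KEYS = ("fj_proximal", "fj_distal", "ds_proximal", "ds_distal", "ft_level")
_INTEGRATION_KEYS = ("dt", "t_max", "tol", "classify_tol")
_EXPERIMENT_KEYS = ("kind", "flatten_level")
_TOP_KEYS = ("seed", "outdir")
_SECTIONS = {
    "model": _MODEL_KEYS,
    "profiles": _PROFILE_KEYS,
    "integration": _INTEGRATION_KEYS,
    "experiment": _EXPERIMENT_KEYS,
}


class ConfigError(ValueError):
    """Configuration file failed to parse or validate; message names the key."""


@dataclass(frozen=True)
class ProfileSettings:
    """Scalar description of the wild-type profiles (None = derived default)."""

    fj_proximal: float | None = None
    fj_distal: float = 1.0
    ds_proximal: float | None = None
    ds_distal: float = 1.0
    ft_level: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    """A complete, serializable run description."""

    params: ModelParameters = field(default_factory=ModelParameters)
    profile_settings: ProfileSettings = field(default_factory=ProfileSettings)
    dt: float = 0.1
    t_max: float = 500.0
    tol: float = 1e-8
    classify_tol: float = CLASSIFY_TOL
    experiment: PerturbationSpec = field(default_factory=PerturbationSpec)
    seed: int = 0
    outdir: str = "results"

    def simulation_config(self) -> SimulationConfig:
        ps = self.profile_settings
        profiles = wildtype_profiles(
            self.params.n_cells,
            fj_proximal=ps.fj_proximal,
            fj_distal=ps.fj_distal,
            ds_proximal=ps.ds_proximal,
            ds_distal=ps.ds_distal,
            ft_level=ps.ft_level,
        )
        return SimulationConfig(
            params=self.params,
            profiles=profiles,
            dt=self.dt,
            t_max=self.t_max,
            tol=self.tol,
            classify_tol=self.classify_tol,
        )


def _flatten(raw: dict) -> dict[tuple[str, str], object]:
    """Resolve sectioned and flat keys into (section, key) pairs, validating names."""
    flat_lookup = {k: s for s, keys in _SECTIONS.items() for k in keys}
    out: dict[tuple[str, str], object] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, v in value.items():
                if sub not in _SECTIONS[key]:
                    raise ConfigError(f"unknown key {key}.{sub}")
                if isinstance(v, dict):
                    raise ConfigError(f"key {key}.{sub} must be a scalar")
                out[(key, sub)] = v
        elif key in _TOP_KEYS:
            out[("", key)] = value
        elif key in flat_lookup:
            out[(flat_lookup[key], key)] = value
        else:
            raise ConfigError(f"unknown key {key}")
    return out


def read_config(path) -> RunConfig:
    """Read a run configuration, filling missing keys from the defaults."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse failure: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    resolved = _flatten(raw)

    def section(name: str) -> dict:
        return {k: v for (s, k), v in resolved.items() if s == name}

    try:
        params = ModelParameters(**section("model"))
        ps = ProfileSettings(**section("profiles"))
        integ = section("integration")
        exp = section("experiment")
        experiment = PerturbationSpec(
            kind=exp.get("kind", "wild_type"),
            flatten_level=exp.get("flatten_level"),
        )
        top = section("")
        return RunConfig(
            params=params,
            profile_settings=ps,
            dt=float(integ.get("dt", 0.1)),
            t_max=float(integ.get("t_max", 500.0)),
            tol=float(integ.get("tol", 1e-8)),
            classify_tol=float(integ.get("classify_tol", CLASSIFY_TOL)),
            experiment=experiment,
            seed=int(top.get("seed", 0)),
            outdir=str(top.get("outdir", "results")),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def write_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig; read_config(write_config(c)) == c."""
    doc = {
        "model": dataclasses.asdict(config.params),
        "profiles": dataclasses.asdict(config.profile_settings),
        "integration": {
            "dt": config.dt,
            "t_max": config.t_max,
            "tol": config.tol,
            "classify_tol": config.classify_tol,
        },
        "experiment": {
            "kind": config.experiment.kind,
            "flatten_level": config.experiment.flatten_level,
        },
        "seed": config.seed,
        "outdir": config.outdir,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_results(result: ExperimentResult, outdir) -> list[Path]:
    """Write cells.tsv, edges.tsv and summary.json for one experiment run.

    Boundary cells (no neighbor on one side) have empty polarity columns.
    Floats are printed at 9 significant digits; re-running the same
    (config, seed) reproduces the files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = result.profiles.n_cells
    state = result.final_state
    ft_u = result.profiles.ft_total - state.ft_p
    ds_u = result.profiles.ds_total - state.ds_p
    pol = result.polarity

    cells_path = outdir / "cells.tsv"
    header = (
        "cell_index\tfj\tds_total\tft_p\tds_p\tft_u\tds_u\tp_ft\tp_ds\tdelta_c\tlabel"
    )
    lines = [header]
    for i in range(n):
        row = [
            str(i + 1),
            _fmt(result.profiles.fj[i]),
            _fmt(result.profiles.ds_total[i]),
            _fmt(state.ft_p[i]),
            _fmt(state.ds_p[i]),
            _fmt(ft_u[i]),
            _fmt(ds_u[i]),
        ]
        if 1 <= i <= n - 2:
            j = i - 1  # interior-cell vector index
            row += [_fmt(pol.p_ft[j]), _fmt(pol.p_ds[j]), _fmt(pol.delta_c[j]), pol.labels[j]]
        else:
            row += ["", "", "", ""]
        lines.append("\t".join(row))
    cells_path.write_text("\n".join(lines) + "\n")

    edges_path = outdir / "edges.tsv"
    lines = ["edge_index\tproximal_cell\tdistal_cell\tc_total\tc_orient_ds_distal\tc_orient_ft_distal"]
    for j in range(n - 1):
        lines.append(
            "\t".join(
                [
                    str(j + 1),
                    str(j + 1),
                    str(j + 2),
                    _fmt(result.edges.c_total[j]),
                    _fmt(result.edges.c_orient_ds_distal[j]),
                    _fmt(result.edges.c_orient_ft_distal[j]),
                ]
            )
        )
    edges_path.write_text("\n".join(lines) + "\n")

    labels, counts = np.unique(pol.labels.astype(str), return_counts=True)
    summary_path = outdir / "summary.json"
    summary = {
        "spec": {
            "kind": result.spec.kind,
            "flatten_level": result.spec.flatten_level,
            "overrides": dict(result.spec.overrides),
        },
        "seed": result.seed,
        "converged": bool(result.converged),
        "convergence_time": result.convergence_time,
        "n_cells": n,
        "label_counts": {str(l): int(c) for l, c in zip(labels, counts)},
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [cells_path, edges_path, summary_path]


_PLOT_EXTENSIONS = (".png", ".svg", ".pdf")


def draw_trapezoids(proximal_heights, distal_heights, path, title: str = "") -> None:
    """Render one trapezoid per cell: left/right heights = proximal/distal edge C."""
    path = Path(path)
    if path.suffix.lower() not in _PLOT_EXTENSIONS:
        raise ValueError(
            f"unknown plot extension {path.suffix!r}; expected one of {_PLOT_EXTENSIONS}"
        )
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure
    from matplotlib.patches import Polygon

    prox = np.asarray(proximal_heights, dtype=float)
    dist = np.asarray(distal_heights, dtype=float)
    if prox.size != dist.size:
        raise ValueError("proximal and distal height vectors must have equal length")
    fig = Figure(figsize=(max(6, prox.size * 0.45), 3.2))
    ax = fig.add_subplot(111)
    for i, (hl, hr) in enumerate(zip(prox, dist)):
        x0, x1 = i + 0.55, i + 1.45
        ax.add_patch(
            Polygon(
                [(x0, 0), (x1, 0), (x1, hr), (x0, hl)],
                closed=True,
                facecolor="firebrick",
                edgecolor="black",
                alpha=0.8,
                linewidth=0.6,
            )
        )
    ax.set_xlim(0.4, prox.size + 0.6)
    top = float(max(prox.max(), dist.max(), 1e-12))
    ax.set_ylim(0, 1.1 * top)
    ax.set_xlabel("cell (proximal → distal)")
    ax.set_ylabel("Ft-Ds heterodimer C")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)


def trapezoid_heights(result: ExperimentResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (proximal, distal) edge concentrations; boundary cells one-sided."""
    c = result.edges.c_total
    n = result.profiles.n_cells
    prox = np.empty(n)
    dist = np.empty(n)
    prox[1:] = c
    dist[:-1] = c
    prox[0] = dist[0]  # proximal-most cell has no proximal edge
    dist[-1] = prox[-1]  # distal-most cell has no distal edge
    return prox, dist


def export_trapezoid_plot(result: ExperimentResult, path) -> Path:
    """Export the per-cell trapezoid visualization of edge heterodimer levels."""
    prox, dist = trapezoid_heights(result)
    draw_trapezoids(prox, dist, path, title=result.spec.kind)
    return Path(path)
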