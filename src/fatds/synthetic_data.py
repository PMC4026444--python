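"""Builders for the model's inputs: expression profiles, initial states, defaults.

The wild-type tissue is a row of N=20 cells with a linearly increasing Fj
activity profile (normalized to 1 in the distal-most cell, ``fj[i] = i/N``
for 1-based i so every cell has strictly positive activity) and a linearly
decreasing total-Ds profile (normalized to 1 in the distal-most cell, with
a proximal excess of slope 0.5 across the row). Total Ft is uniform at 1.
Initial phosphorylated levels are uniform random within each cell's
conservation bound, mirroring a tissue with no pre-existing coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ExpressionProfiles, ModelParameters, PhosphoState

__all__ = [
    "ProfileSpec",
    "linear_profile",
    "uniform_profile",
    "wildtype_profiles",
    "random_initial_state",
    "default_wildtype_config",
]

#: default proximal excess of total Ds relative to the distal-most cell
DS_SLOPE = 0.5


@dataclass(frozen=True)
class ProfileSpec:
    """Declarative description of a per-cell expression profile."""

    shape: str  # "linear" or "uniform"
    proximal_value: float
    distal_value: float
    n_cells: int

    def build(self) -> np.ndarray:
        if self.shape == "linear":
            return linear_profile(self.n_cells, self.proximal_value, self.distal_value)
        if self.shape == "uniform":
            if self.proximal_value != self.distal_value:
                raise ValueError("uniform profile requires equal endpoint values")
            return uniform_profile(self.n_cells, self.proximal_value)
        raise ValueError(f"unknown profile shape {self.shape!r}")


def linear_profile(n_cells: int, proximal_value: float, distal_value: float) -> np.ndarray:
    """Arithmetic sequence from the proximal to the distal endpoint, inclusive."""
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    if proximal_value < 0 or distal_value < 0:
        raise ValueError("profile values must be non-negative")
    return np.linspace(proximal_value, distal_value, n_cells)


def uniform_profile(n_cells: int, value: float) -> np.ndarray:
    """Constant per-cell profile."""
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    if value < 0:
        raise ValueError("profile value must be non-negative")
    return np.full(n_cells, float(value))


def wildtype_profiles(
    n_cells: int = 20,
    *,
    fj_proximal: float | None = None,
    fj_distal: float = 1.0,
    ds_proximal: float | None = None,
    ds_distal: float = 1.0,
    ft_level: float = 1.0,
) -> ExpressionProfiles:
    """Wild-type expression profiles for a row of ``n_cells`` cells.

    Defaults follow the normalized conventions: ``fj[i] = i/N`` (so the
    proximal endpoint is ``1/N`` and the distal endpoint 1), total Ds
    decreasing linearly from ``1 + DS_SLOPE * (N-1)/N`` to 1, and uniform
    total Ft.
    """
    if fj_proximal is None:
        fj_proximal = fj_distal / n_cells
    if ds_proximal is None:
        ds_proximal = ds_distal + DS_SLOPE * (n_cells - 1) / n_cells
    return ExpressionProfiles(
        fj=linear_profile(n_cells, fj_proximal, fj_distal),
        ds_total=linear_profile(n_cells, ds_proximal, ds_distal),
        ft_total=uniform_profile(n_cells, ft_level),
    )


def random_initial_state(profiles: ExpressionProfiles, seed: int) -> PhosphoState:
    """Seeded uniform-random initial phosphorylated levels.

    ``ft_p[i] ~ U(0, ft_total[i])`` and ``ds_p[i] ~ U(0, ds_total[i])``,
    independently per cell; identical (profiles, seed) give bit-identical
    states.
    """
    rng = np.random.default_rng(seed)
    ft_p = rng.uniform(0.0, profiles.ft_total)
    ds_p = rng.uniform(0.0, profiles.ds_total)
    return PhosphoState(ft_p=ft_p, ds_p=ds_p)


def default_wildtype_config() -> tuple[ModelParameters, ExpressionProfiles]:
    """The reference 20-cell wild-type configuration.

    Parameters: alpha_ft = alpha_ds = 2, beta_ft = beta_ds = 0.1,
    Hill n = 1, K = 250, k_on = 1, k_off = 0.1, mu = 1.
    """
    params = ModelParameters()
    return params, wildtype_profiles(params.n_cells)
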