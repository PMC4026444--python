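"""Core kinetics of the Fat-Dachsous-Four-jointed system in a 1-D cell row.

The model describes a single proximo-distal row of epithelial cells (as in
the *Drosophila* wing). Each cell ``i`` carries the atypical cadherins Fat
(Ft) and Dachsous (Ds), which the Golgi kinase Four-jointed (Fj)
phosphorylates. Fj activity acts through a Hill function of the local Fj
level, so a tissue-level Fj gradient translates into graded phosphorylation.
The only dynamical variables per cell are the phosphorylated levels
``ft_p[i]`` and ``ds_p[i]``; the unphosphorylated pools follow from
conservation of the (fixed) totals.

Phosphorylation kinetics are linear and cell-autonomous::

    d ft_p[i]/dt = alpha_ft * H(fj[i]) * (ft_total[i] - ft_p[i]) - beta_ft * ft_p[i]
    d ds_p[i]/dt = alpha_ds * H(fj[i]) * (ds_total[i] - ds_p[i]) - beta_ds * ds_p[i]

with ``H(fj) = fj**n / (K**n + fj**n)``. Because the equations are linear
with constant coefficients, both the steady state and the full time
evolution have closed forms (:func:`steady_state_phospho`,
:func:`analytic_relaxation`); these serve as exact oracles for the numerical
integrators in :mod:`fatds.dynamics`.

Units are normalized: Ft levels by the (uniform) total Ft per cell, Ds and
Fj levels by their totals in the most distal cell of the row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "ExpressionProfiles",
    "PhosphoState",
    "hill_activity",
    "unphosphorylated_levels",
    "phospho_rates",
    "steady_state_phospho",
    "analytic_relaxation",
]


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and coupling parameters of the model.

    Defaults are the reference parameter set: symmetric phosphorylation
    kinetics for Ft and Ds (alpha=2, beta=0.1 per unit time), a first-order
    Hill coupling with half-saturation K=250 (so normalized Fj levels in
    [0, 1] sit in the near-linear regime), heterodimer binding k_on=1,
    k_off=0.1, and equal weighting (mu=1) of the two polarity mechanisms.

    ``hill_n_ds`` / ``hill_k_ds`` optionally give the Ds-phosphorylation
    coupling its own Hill parameters; when ``None`` the shared values apply
    to both substrates.
    """

    n_cells: int = 20
    alpha_ft: float = 2.0
    beta_ft: float = 0.1
    alpha_ds: float = 2.0
    beta_ds: float = 0.1
    hill_n: float = 1.0
    hill_k: float = 250.0
    k_on: float = 1.0
    k_off: float = 0.1
    mu: float = 1.0
    hill_n_ds: float | None = None
    hill_k_ds: float | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3 (at least one interior cell)")
        for name in ("alpha_ft", "alpha_ds", "k_on", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("beta_ft", "beta_ds", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (steady states must exist)")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.hill_k <= 0:
            raise ValueError("hill_k must be > 0")
        if self.hill_n_ds is not None and self.hill_n_ds < 1:
            raise ValueError("hill_n_ds must be >= 1")
        if self.hill_k_ds is not None and self.hill_k_ds <= 0:
            raise ValueError("hill_k_ds must be > 0")

    @property
    def hill_ft(self) -> tuple[float, float]:
        """(n, K) of the Ft-phosphorylation Hill coupling."""
        return self.hill_n, self.hill_k

    @property
    def hill_ds(self) -> tuple[float, float]:
        """(n, K) of the Ds-phosphorylation Hill coupling."""
        n = self.hill_n if self.hill_n_ds is None else self.hill_n_ds
        k = self.hill_k if self.hill_k_ds is None else self.hill_k_ds
        return n, k

    def with_overrides(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExpressionProfiles:
    """Per-cell expression vectors: Fj activity, total Ds, total Ft.

    Index 0 is the proximal-most cell; the last index is the distal-most.
    In the wild-type construction ``fj`` increases and ``ds_total``
    decreases proximal to distal while ``ft_total`` is uniform, but the
    type itself only requires non-negative entries of equal length.
    """

    fj: np.ndarray
    ds_total: np.ndarray
    ft_total: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fj", _as_vector(self.fj, "fj"))
        object.__setattr__(self, "ds_total", _as_vector(self.ds_total, "ds_total"))
        object.__setattr__(self, "ft_total", _as_vector(self.ft_total, "ft_total"))
        n = self.fj.size
        if self.ds_total.size != n or self.ft_total.size != n:
            raise ValueError("fj, ds_total and ft_total must have equal length")
        for name in ("fj", "ds_total", "ft_total"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.fj.size


@dataclass(frozen=True)
class PhosphoState:
    """Phosphorylated Ft and Ds levels per cell (the dynamical variables)."""

    ft_p: np.ndarray
    ds_p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ft_p", _as_vector(self.ft_p, "ft_p"))
        object.__setattr__(self, "ds_p", _as_vector(self.ds_p, "ds_p"))
        if self.ft_p.size != self.ds_p.size:
            raise ValueError("ft_p and ds_p must have equal length")

    @property
    def n_cells(self) -> int:
        return self.ft_p.size


def _check_lengths(state: PhosphoState, profiles: ExpressionProfiles) -> None:
    if state.n_cells != profiles.n_cells:
        raise ValueError(
            f"state has {state.n_cells} cells but profiles have {profiles.n_cells}"
        )


def validate_state(state: PhosphoState, profiles: ExpressionProfiles) -> None:
    """Check the conservation bounds 0 <= ft_p <= ft_total, 0 <= ds_p <= ds_total."""
    _check_lengths(state, profiles)
    if np.any(state.ft_p < 0) or np.any(state.ft_p > profiles.ft_total):
        raise ValueError("ft_p violates conservation bounds [0, ft_total]")
    if np.any(state.ds_p < 0) or np.any(state.ds_p > profiles.ds_total):
        raise ValueError("ds_p violates conservation bounds [0, ds_total]")


def hill_activity(fj_level, hill_n: float, hill_k: float):
    """Fractional kinase activity of Fj at a given (normalized) Fj level.

    Evaluates ``fj**n / (K**n + fj**n)``: a monotonically increasing
    saturating response, equal to 1/2 exactly at ``fj_level == hill_k``.
    Accepts scalars or arrays.
    """
    if hill_k <= 0:
        raise ValueError("hill_k must be > 0")
    if hill_n < 1:
        raise ValueError("hill_n must be >= 1")
    fj = np.asarray(fj_level, dtype=float)
    if not np.all(np.isfinite(fj)):
        raise ValueError("fj_level must be finite")
    if np.any(fj < 0):
        raise ValueError("fj_level must be non-negative")
    # work with the ratio to avoid overflow for large fj or n
    r = np.power(fj / hill_k, hill_n)
    out = r / (1.0 + r)
    if np.isscalar(fj_level) or np.ndim(fj_level) == 0:
        return float(out)
    return out


def unphosphorylated_levels(
    state: PhosphoState, profiles: ExpressionProfiles
) -> tuple[np.ndarray, np.ndarray]:
    """Unphosphorylated Ft and Ds per cell by conservation of totals."""
    validate_state(state, profiles)
    return profiles.ft_total - state.ft_p, profiles.ds_total - state.ds_p


def _activation_rates(
    profiles: ExpressionProfiles, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Effective phosphorylation rates a = alpha * H(fj) per cell, per substrate."""
    n_ft, k_ft = params.hill_ft
    n_ds, k_ds = params.hill_ds
    a_ft = params.alpha_ft * hill_activity(profiles.fj, n_ft, k_ft)
    a_ds = params.alpha_ds * hill_activity(profiles.fj, n_ds, k_ds)
    return np.asarray(a_ft, dtype=float), np.asarray(a_ds, dtype=float)


def phospho_rates(
    state: PhosphoState, profiles: ExpressionProfiles, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (d ft_p/dt, d ds_p/dt) of the phosphorylation ODEs.

    Cells are uncoupled here: phosphorylation happens in the Golgi of each
    cell, driven only by that cell's own Fj activity.
    """
    _check_lengths(state, profiles)
    if profiles.n_cells != params.n_cells:
        raise ValueError(
            f"profiles have {profiles.n_cells} cells but params expect {params.n_cells}"
        )
    a_ft, a_ds = _activation_rates(profiles, params)
    dft = a_ft * (profiles.ft_total - state.ft_p) - params.beta_ft * state.ft_p
    dds = a_ds * (profiles.ds_total - state.ds_p) - params.beta_ds * state.ds_p
    return dft, dds


def steady_state_phospho(
    profiles: ExpressionProfiles, params: ModelParameters
) -> PhosphoState:
    """Closed-form steady state of the phosphorylation ODEs.

    Per cell, ``ft_p* = ft_total * a / (a + beta_ft)`` with
    ``a = alpha_ft * H(fj)``, and analogously for Ds. The state is the
    unique, globally attracting fixed point (beta > 0 guarantees
    existence).
    """
    a_ft, a_ds = _activation_rates(profiles, params)
    ft_p = profiles.ft_total * a_ft / (a_ft + params.beta_ft)
    ds_p = profiles.ds_total * a_ds / (a_ds + params.beta_ds)
    return PhosphoState(ft_p=ft_p, ds_p=ds_p)


def analytic_relaxation(
    initial: PhosphoState,
    profiles: ExpressionProfiles,
    params: ModelParameters,
    t: float,
) -> PhosphoState:
    """Exact solution of the phosphorylation ODEs at time ``t``.

    Each component relaxes exponentially toward its steady state:
    ``x(t) = x* + (x(0) - x*) * exp(-(a + beta) * t)``.
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError("t must be a non-negative finite scalar")
    validate_state(initial, profiles)
    a_ft, a_ds = _activation_rates(profiles, params)
    star = steady_state_phospho(profiles, params)
    # convex-combination form: exact identity at t=0, exact steady state as t→∞
    w_ft = np.exp(-(a_ft + params.beta_ft) * t)
    w_ds = np.exp(-(a_ds + params.beta_ds) * t)
    ft_p = initial.ft_p * w_ft + star.ft_p * (1.0 - w_ft)
    ds_p = initial.ds_p * w_ds + star.ds_p * (1.0 - w_ds)
    return PhosphoState(ft_p=ft_p, ds_p=ds_p)
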