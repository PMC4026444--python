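"""Forward-difference time integration of the phosphorylation and edge ODEs.

The shipped integrator is explicit (forward) Euler. The phosphorylation
equations are linear and uncoupled, so the scheme is stable whenever
``dt < 2 / max(a + beta, k_off)`` where ``a = alpha * H(fj)`` is the largest
effective phosphorylation rate over cells and substrates;
:func:`stability_bound` computes that limit and :func:`integrate_phospho`
refuses step sizes that violate it. Accuracy is first order in ``dt``; the
closed forms in :mod:`fatds.model_core` give the exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    ExpressionProfiles,
    ModelParameters,
    PhosphoState,
    _activation_rates,
    phospho_rates,
    validate_state,
)

__all__ = [
    "Trajectory",
    "EdgeTrajectory",
    "StabilityError",
    "IntegrationError",
    "stability_bound",
    "integrate_phospho",
    "integrate_edges",
    "check_steady",
]


class StabilityError(ValueError):
    """Raised when the requested step size exceeds the explicit-Euler limit."""


class IntegrationError(RuntimeError):
    """Raised when non-finite values appear during integration."""


@dataclass(frozen=True)
class Trajectory:
    """Stored time course of a phosphorylation integration.

    ``ft_p`` and ``ds_p`` have shape (n_times, n_cells); storage is thinned
    (every ``store_every``-th Euler step) but always includes t=0 and the
    final state. ``converged`` reports whether max|rate| fell below the
    integration tolerance; ``convergence_time`` is the earliest stored time
    at which it had.
    """

    times: np.ndarray
    ft_p: np.ndarray
    ds_p: np.ndarray
    profiles: ExpressionProfiles
    params: ModelParameters
    converged: bool
    convergence_time: float | None

    @property
    def n_times(self) -> int:
        return self.times.size

    def state_at(self, index: int) -> PhosphoState:
        return PhosphoState(ft_p=self.ft_p[index], ds_p=self.ds_p[index])

    @property
    def final_state(self) -> PhosphoState:
        return self.state_at(-1)


@dataclass(frozen=True)
class EdgeTrajectory:
    """Stored time course of edge heterodimer concentrations, shape (n_times, n_edges)."""

    times: np.ndarray
    c: np.ndarray


def stability_bound(profiles: ExpressionProfiles, params: ModelParameters) -> float:
    """Largest stable explicit-Euler step for the phospho + edge equations.

    All equations are linear relaxations; the fastest rate over cells and
    species (``alpha * H(fj) + beta`` for either substrate, ``k_off`` for the
    edges) sets the limit ``dt_max = 2 / rate_max``.
    """
    a_ft, a_ds = _activation_rates(profiles, params)
    rate_max = max(
        float(np.max(a_ft + params.beta_ft)),
        float(np.max(a_ds + params.beta_ds)),
        params.k_off,
    )
    return 2.0 / rate_max


def integrate_phospho(
    initial: PhosphoState,
    profiles: ExpressionProfiles,
    params: ModelParameters,
    dt: float = 0.1,
    t_max: float = 500.0,
    tol: float = 1e-8,
    *,
    early_stop: bool = True,
    store_every: int = 10,
) -> Trajectory:
    """Integrate the phosphorylation ODEs by forward Euler.

    With ``early_stop`` the run terminates as soon as the largest absolute
    rate over cells and species drops below ``tol``; otherwise it runs to
    ``t_max`` and ``converged`` simply records whether the criterion was met
    along the way. Running the full window drives the state to the
    floating-point fixed point, which the perturbation experiments rely on
    when classifying near-zero asymmetries.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bound = stability_bound(profiles, params)
    if dt >= bound:
        raise StabilityError(
            f"dt={dt} violates the explicit-Euler stability limit {bound:.6g}"
        )
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    validate_state(initial, profiles)

    ft = initial.ft_p.copy()
    ds = initial.ds_p.copy()
    times = [0.0]
    ft_hist = [ft.copy()]
    ds_hist = [ds.copy()]
    converged = False
    convergence_time: float | None = None

    n_steps = int(np.ceil(t_max / dt - 1e-12))
    for k in range(n_steps + 1):
        t = k * dt
        state = PhosphoState(ft_p=ft, ds_p=ds)
        dft, dds = phospho_rates(state, profiles, params)
        rate_max = max(float(np.max(np.abs(dft))), float(np.max(np.abs(dds))))
        if not np.isfinite(rate_max):
            raise IntegrationError(f"non-finite rates at t={t}")
        if rate_max < tol and not converged:
            converged = True
            convergence_time = t
            if early_stop:
                if times[-1] != t:
                    times.append(t)
                    ft_hist.append(ft.copy())
                    ds_hist.append(ds.copy())
                break
        if k == n_steps:
            break
        ft = ft + dt * dft
        ds = ds + dt * dds
        t_next = (k + 1) * dt
        if (k + 1) % store_every == 0 or k + 1 == n_steps:
            times.append(t_next)
            ft_hist.append(ft.copy())
            ds_hist.append(ds.copy())

    if times[-1] < n_steps * dt and not (early_stop and converged):
        times.append(n_steps * dt)
        ft_hist.append(ft.copy())
        ds_hist.append(ds.copy())

    return Trajectory(
        times=np.asarray(times),
        ft_p=np.vstack(ft_hist),
        ds_p=np.vstack(ds_hist),
        profiles=profiles,
        params=params,
        converged=converged,
        convergence_time=convergence_time,
    )


def _interp_states(traj: Trajectory, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Phospho state at time t, linearly interpolated between stored samples."""
    times = traj.times
    if t <= times[0]:
        return traj.ft_p[0], traj.ds_p[0]
    if t >= times[-1]:
        return traj.ft_p[-1], traj.ds_p[-1]
    j = int(np.searchsorted(times, t, side="right"))
    w = (t - times[j - 1]) / (times[j] - times[j - 1])
    ft = traj.ft_p[j - 1] * (1 - w) + traj.ft_p[j] * w
    ds = traj.ds_p[j - 1] * (1 - w) + traj.ds_p[j] * w
    return ft, ds


def integrate_edges(
    phospho_trajectory: Trajectory,
    params: ModelParameters,
    initial_edges: np.ndarray,
    dt: float = 0.1,
    *,
    store_every: int = 10,
) -> EdgeTrajectory:
    """Integrate the edge heterodimer ODEs alongside a phospho trajectory.

    For the edge between cells i and i+1::

        dC/dt = k_on * (ft_p[i] * ds_u[i+1] + ds_u[i] * ft_p[i+1]) - k_off * C

    The phospho state driving the binding is read from the (possibly
    thinned) stored trajectory by linear interpolation. Heterodimer
    formation does not feed back on the monomer pools: phosphorylation
    happens in the Golgi, binding at the cell edges.
    """
    traj = phospho_trajectory
    n_cells = traj.profiles.n_cells
    c = np.asarray(initial_edges, dtype=float).copy()
    if c.size != n_cells - 1:
        raise ValueError(f"expected {n_cells - 1} interior edges, got {c.size}")
    if np.any(c < 0):
        raise ValueError("edge concentrations must be non-negative")
    if dt <= 0 or dt >= 2.0 / params.k_off:
        raise StabilityError(
            f"dt={dt} violates the edge stability limit {2.0 / params.k_off:.6g}"
        )

    t_end = float(traj.times[-1])
    n_steps = int(np.ceil(t_end / dt - 1e-12))
    times = [0.0]
    c_hist = [c.copy()]
    ds_total = traj.profiles.ds_total
    for k in range(n_steps):
        t = k * dt
        ft_p, ds_p = _interp_states(traj, t)
        ds_u = ds_total - ds_p
        rate = (
            params.k_on * (ft_p[:-1] * ds_u[1:] + ds_u[:-1] * ft_p[1:])
            - params.k_off * c
        )
        if not np.all(np.isfinite(rate)):
            raise IntegrationError(f"non-finite edge rates at t={t}")
        c = c + dt * rate
        if (k + 1) % store_every == 0 or k + 1 == n_steps:
            times.append((k + 1) * dt)
            c_hist.append(c.copy())
    return EdgeTrajectory(times=np.asarray(times), c=np.vstack(c_hist))


def check_steady(trajectory: Trajectory, tol: float) -> tuple[bool, int | None]:
    """Earliest stored state whose rates all lie below ``tol``.

    Returns ``(found, index)``; deterministic in the stored trajectory.
    """
    if trajectory.n_times == 0:
        raise ValueError("trajectory is empty")
    for idx in range(trajectory.n_times):
        dft, dds = phospho_rates(
            trajectory.state_at(idx), trajectory.profiles, trajectory.params
        )
        if max(np.max(np.abs(dft)), np.max(np.abs(dds))) < tol:
            return True, idx
    return False, None
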