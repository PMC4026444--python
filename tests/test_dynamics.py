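"""Tests of the forward-Euler integrators against the exact closed forms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fatds.dynamics import (
    StabilityError,
    check_steady,
    integrate_edges,
    integrate_phospho,
    stability_bound,
)
from fatds.heterodimer import edge_steady_state
from fatds.model_core import (
    ExpressionProfiles,
    ModelParameters,
    PhosphoState,
    analytic_relaxation,
    steady_state_phospho,
)
from fatds.synthetic_data import default_wildtype_config, random_initial_state


class TestStabilityBound:
    def test_default_config_value(self, default_config):
        # fastest rate: alpha*H(1) + beta = 2/251 + 0.1
        bound = stability_bound(default_config.profiles, default_config.params)
        assert bound == pytest.approx(2.0 / (2.0 / 251.0 + 0.1), rel=1e-12)
        assert bound == pytest.approx(18.5, abs=0.1)

    def test_pure_decay_bound(self):
        profiles = ExpressionProfiles(
            fj=np.zeros(3), ds_total=np.ones(3), ft_total=np.ones(3)
        )
        params = ModelParameters(n_cells=3, alpha_ft=0.0, alpha_ds=0.0,
                                 beta_ft=1.0, beta_ds=1.0, k_off=0.1)
        assert stability_bound(profiles, params) == pytest.approx(2.0)

    def test_doubling_rates_halves_bound(self, default_config):
        p = default_config.params
        doubled = p.with_overrides(
            alpha_ft=2 * p.alpha_ft, beta_ft=2 * p.beta_ft,
            alpha_ds=2 * p.alpha_ds, beta_ds=2 * p.beta_ds, k_off=2 * p.k_off,
        )
        assert stability_bound(default_config.profiles, doubled) == pytest.approx(
            stability_bound(default_config.profiles, p) / 2.0
        )


class TestIntegratePhospho:
    def test_fixed_point_converges_immediately(self, default_config):
        star = steady_state_phospho(default_config.profiles, default_config.params)
        traj = integrate_phospho(star, default_config.profiles, default_config.params)
        assert traj.converged
        assert traj.convergence_time == 0.0
        np.testing.assert_array_equal(traj.final_state.ft_p, star.ft_p)

    def test_matches_closed_form_oracle(self, default_config):
        init = random_initial_state(default_config.profiles, seed=7)
        traj = integrate_phospho(init, default_config.profiles, default_config.params,
                                 dt=0.1, t_max=500.0, tol=1e-8)
        assert traj.converged
        star = steady_state_phospho(default_config.profiles, default_config.params)
        assert np.max(np.abs(traj.final_state.ft_p - star.ft_p)) < 1e-6
        assert np.max(np.abs(traj.final_state.ds_p - star.ds_p)) < 1e-6
        # trajectory tracks the exact relaxation to first-order accuracy
        for i in (1, traj.n_times // 2, traj.n_times - 1):
            ref = analytic_relaxation(init, default_config.profiles,
                                      default_config.params, float(traj.times[i]))
            assert np.max(np.abs(traj.ft_p[i] - ref.ft_p)) < 5e-3

    def test_first_order_convergence_in_dt(self, default_config):
        init = random_initial_state(default_config.profiles, seed=0)

        def max_err(dt):
            traj = integrate_phospho(init, default_config.profiles,
                                     default_config.params, dt=dt, t_max=100.0,
                                     tol=1e-12, early_stop=False)
            return max(
                np.max(np.abs(traj.ft_p[i] - analytic_relaxation(
                    init, default_config.profiles, default_config.params,
                    float(t)).ft_p))
                for i, t in enumerate(traj.times)
            )

        e1, e2 = max_err(0.1), max_err(0.05)
        assert e2 / e1 == pytest.approx(0.5, abs=0.1)

    def test_stability_violation_refused(self, default_config):
        init = random_initial_state(default_config.profiles, seed=0)
        bad_dt = 2.0 * stability_bound(default_config.profiles, default_config.params)
        with pytest.raises(StabilityError):
            integrate_phospho(init, default_config.profiles, default_config.params,
                              dt=bad_dt)

    def test_times_strictly_increasing_from_zero(self, default_config):
        init = random_initial_state(default_config.profiles, seed=2)
        traj = integrate_phospho(init, default_config.profiles, default_config.params)
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)

    @given(seed=st.integers(0, 30))
    def test_conservation_bounds_preserved(self, seed):
        """Every stored Euler state stays inside [0, total] for both species."""
        params, profiles = default_wildtype_config()
        init = random_initial_state(profiles, seed)
        traj = integrate_phospho(init, profiles, params, dt=1.0, t_max=50.0)
        assert np.all(traj.ft_p >= 0) and np.all(traj.ft_p <= profiles.ft_total)
        assert np.all(traj.ds_p >= 0) and np.all(traj.ds_p <= profiles.ds_total)

    def test_initial_condition_independence(self, default_config):
        finals = []
        for seed in (11, 12):
            init = random_initial_state(default_config.profiles, seed)
            traj = integrate_phospho(init, default_config.profiles,
                                     default_config.params, early_stop=False)
            finals.append(traj.final_state)
        assert np.max(np.abs(finals[0].ft_p - finals[1].ft_p)) < 1e-8
        assert np.max(np.abs(finals[0].ds_p - finals[1].ds_p)) < 1e-8


class TestIntegrateEdges:
    def _held_trajectory(self, config, state):
        """A two-point trajectory holding the phospho state constant."""
        return integrate_phospho(state, config.profiles, config.params,
                                 dt=0.1, t_max=200.0, tol=1e-30, early_stop=False)

    def test_relaxes_to_edge_steady_state(self, default_config):
        star = steady_state_phospho(default_config.profiles, default_config.params)
        traj = self._held_trajectory(default_config, star)
        edges = integrate_edges(traj, default_config.params,
                                np.zeros(default_config.profiles.n_cells - 1), dt=0.1)
        target = edge_steady_state(star, default_config.profiles, default_config.params)
        assert np.max(np.abs(edges.c[-1] - target.c_total)) < 1e-6

    def test_pure_dissociation_decay(self, default_config):
        # kinase-dead tissue started unphosphorylated: ft_p stays 0, so the
        # edge equation is pure dissociation
        import dataclasses

        dead = dataclasses.replace(
            default_config,
            params=default_config.params.with_overrides(alpha_ft=0.0, alpha_ds=0.0),
        )
        zero = PhosphoState(
            ft_p=np.zeros(dead.profiles.n_cells),
            ds_p=np.zeros(dead.profiles.n_cells),
        )
        traj = self._held_trajectory(dead, zero)
        c0 = np.full(dead.profiles.n_cells - 1, 2.0)
        edges = integrate_edges(traj, dead.params, c0, dt=0.1)
        k_off, dt = dead.params.k_off, 0.1
        for i, t in enumerate(edges.times):
            expected = c0 * (1 - k_off * dt) ** round(t / dt)
            np.testing.assert_allclose(edges.c[i], expected, rtol=1e-9)

    def test_steady_initial_edges_stay_constant(self, default_config):
        star = steady_state_phospho(default_config.profiles, default_config.params)
        target = edge_steady_state(star, default_config.profiles, default_config.params)
        traj = self._held_trajectory(default_config, star)
        edges = integrate_edges(traj, default_config.params, target.c_total, dt=0.1)
        np.testing.assert_allclose(edges.c[-1], target.c_total, rtol=1e-12)

    def test_wrong_edge_count_rejected(self, default_config):
        star = steady_state_phospho(default_config.profiles, default_config.params)
        traj = self._held_trajectory(default_config, star)
        with pytest.raises(ValueError):
            integrate_edges(traj, default_config.params, np.zeros(5), dt=0.1)


class TestCheckSteady:
    def test_fixed_point_detected_at_first_index(self, default_config):
        star = steady_state_phospho(default_config.profiles, default_config.params)
        traj = integrate_phospho(star, default_config.profiles, default_config.params)
        found, idx = check_steady(traj, tol=1e-8)
        assert found and idx == 0

    def test_truncated_run_not_steady(self, default_config):
        init = random_initial_state(default_config.profiles, seed=5)
        traj = integrate_phospho(init, default_config.profiles, default_config.params,
                                 dt=0.1, t_max=1.0, tol=1e-12)
        found, idx = check_steady(traj, tol=1e-8)
        assert not found and idx is None

    def test_default_run_converges_within_t_max(self, default_config):
        init = random_initial_state(default_config.profiles, seed=5)
        traj = integrate_phospho(init, default_config.profiles, default_config.params,
                                 dt=0.1, t_max=500.0, tol=1e-8)
        assert traj.converged
        assert traj.convergence_time is not None
        assert traj.convergence_time <= 500.0
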