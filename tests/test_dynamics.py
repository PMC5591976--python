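import math

import numpy as np
import pytest

from kroghsim.diffusion import solve_sigma
from kroghsim.dynamics import State, initial_state, rhs, rk4_step, simulate
from kroghsim.grid import build_grid
from kroghsim.oracles import exponential_growth, point_kill_phi
from kroghsim.parameters import ModelParams

COARSE = dict(n=101)  # cheap spatial resolution for fast coupled runs


def point_state(phi=1.0, U=0.0, sigma=1.0) -> State:
    """Single-node state with a frozen drug value (point model)."""
    return State(t=0.0, phi=np.array([phi]), U=np.array([U]), sigma=np.array([sigma]))


def integrate_point(t_end: float, dt: float, alpha: float = 0.0, sigma: float = 1.0) -> State:
    state = point_state(sigma=sigma)
    for _ in range(int(round(t_end / dt))):
        state = rk4_step(state, dt, alpha)
    return state


class TestRhs:
    @pytest.mark.parametrize(
        "phi, U, sigma, alpha, dphi, dU",
        [
            (1.0, 0.0, 1.0, 0.3, 0.3, 1.0),      # initial instant
            (0.0, 5.0, 1.0, 0.3, 0.0, 0.0),      # extinct tissue stays extinct
            (2.0, 0.5, 0.25, 0.0, -1.0, 0.5),    # hand arithmetic
        ],
    )
    def test_pointwise_derivatives(self, phi, U, sigma, alpha, dphi, dU):
        got_dphi, got_dU = rhs(np.array([phi]), np.array([U]), np.array([sigma]), alpha)
        assert got_dphi[0] == pytest.approx(dphi, rel=1e-14)
        assert got_dU[0] == pytest.approx(dU, rel=1e-14)

    def test_quiescence_when_uptake_balances_growth(self):
        dphi, _ = rhs(np.array([0.8]), np.array([0.2]), np.array([0.5]), alpha=0.2)
        assert dphi[0] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rhs(np.ones(3), np.ones(2), np.ones(3), 0.0)


class TestRK4Step:
    def test_drug_free_growth_is_exponential(self):
        dt, steps, alpha = 0.01, 300, 0.3
        state = point_state(sigma=0.0)
        for _ in range(steps):
            state = rk4_step(state, dt, alpha)
        expected = exponential_growth(alpha, steps * dt)
        assert state.phi[0] == pytest.approx(float(expected), rel=1e-12)

    def test_frozen_drug_kill_matches_closed_form(self):
        state = integrate_point(t_end=2.0, dt=1e-3)
        phi_ref, U_ref = point_kill_phi(2.0)
        assert state.phi[0] == pytest.approx(float(phi_ref), abs=1e-11)
        assert state.U[0] == pytest.approx(float(U_ref), abs=1e-11)

    def test_fourth_order_time_convergence(self):
        errors = []
        for dt in (4e-3, 2e-3, 1e-3):
            state = integrate_point(t_end=2.0, dt=dt)
            errors.append(abs(state.phi[0] - float(point_kill_phi(2.0)[0])))
        orders = [math.log2(errors[i] / errors[i + 1]) for i in range(2)]
        assert all(abs(o - 4.0) < 0.5 for o in orders)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            rk4_step(point_state(), 0.0, 0.3)

    def test_oversized_step_reported(self):
        state = point_state(phi=1.0, U=1e8, sigma=1.0)
        with pytest.raises(RuntimeError, match="reduce dt|time step too large"):
            rk4_step(state, 10.0, 0.0)


class TestSimulate:
    def test_initial_mass_ratio_is_one(self):
        mp = ModelParams(alpha=0.3, rb_over_L=0.102, bvf=0.01)
        res = simulate(mp, build_grid(mp, **COARSE), t_end=0.1, dt=0.01)
        assert res.f[0] == pytest.approx(1.0, abs=1e-12)

    def test_no_growth_run_is_monotone_decreasing(self):
        mp = ModelParams(alpha=0.0, rb_over_L=0.102, bvf=0.01)
        res = simulate(mp, build_grid(mp, **COARSE), t_end=3.0, dt=5e-3)
        assert np.all(np.diff(res.f) <= 1e-12)

    def test_uptake_never_decreases(self):
        mp = ModelParams(alpha=0.7, rb_over_L=0.102, bvf=0.01)
        res = simulate(mp, build_grid(mp, **COARSE), t_end=3.0, dt=5e-3)
        assert np.all(np.diff(res.U_series, axis=0) >= -1e-15)

    def test_snapshots_recorded_near_requested_times(self):
        mp = ModelParams(alpha=0.3, rb_over_L=0.102, bvf=0.01)
        res = simulate(mp, build_grid(mp, **COARSE), t_end=1.0, dt=0.01,
                       snapshot_times=(0.0, 0.5))
        assert len(res.snapshots) == 2
        assert res.snapshots[0].t == 0.0
        assert res.snapshots[1].t == pytest.approx(0.5, abs=0.05)

    def test_stage_frozen_drug_is_consistent_with_per_stage_refresh(self):
        """Refreshing sigma once per step vs per RK4 stage: difference stays
        below the spatial discretization scale."""
        mp = ModelParams(alpha=0.3, rb_over_L=0.102, bvf=0.01)
        grid = build_grid(mp, **COARSE)
        dt, t_end = 0.01, 2.0

        res = simulate(mp, grid, t_end=t_end, dt=dt, record_every=1)

        # reference: re-solve the drug field at every RK4 stage
        phi = np.ones(grid.n)
        U = np.zeros(grid.n)
        for _ in range(int(round(t_end / dt))):
            def f(p, u):
                s = solve_sigma(grid, np.maximum(p, 0.0)).sigma
                return rhs(np.maximum(p, 0.0), u, s, mp.alpha)
            k1p, k1u = f(phi, U)
            k2p, k2u = f(phi + 0.5 * dt * k1p, U + 0.5 * dt * k1u)
            k3p, k3u = f(phi + 0.5 * dt * k2p, U + 0.5 * dt * k2u)
            k4p, k4u = f(phi + dt * k3p, U + dt * k3u)
            phi = np.maximum(phi + dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p), 0.0)
            U = U + dt / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)

        from kroghsim.observables import mass_ratio

        f_ref = mass_ratio(grid, phi)
        assert res.f[-1] == pytest.approx(f_ref, abs=2e-4)

    def test_invalid_horizon_rejected(self):
        mp = ModelParams(alpha=0.3, rb_over_L=0.102, bvf=0.01)
        grid = build_grid(mp, **COARSE)
        with pytest.raises(ValueError):
            simulate(mp, grid, t_end=-1.0, dt=0.01)

    def test_initial_state_consistency(self):
        mp = ModelParams(alpha=0.3, rb_over_L=0.102, bvf=0.01)
        grid = build_grid(mp, **COARSE)
        s = initial_state(grid)
        assert np.all(s.phi == 1.0) and np.all(s.U == 0.0)
        np.testing.assert_allclose(s.sigma, solve_sigma(grid, s.phi).sigma)
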