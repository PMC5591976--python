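"""Time integration of the cell-density / cumulative-uptake system.

The cell density obeys the integro-differential balance

    dphi/dt = phi * (alpha - U),      U(r, t) = int_0^t sigma * phi dtau,

between exponential proliferation at rate ``alpha`` and a kill rate
proportional to the cumulative drug uptake ``U``.  Promoting the history
integral to a state variable (``dU/dt = sigma * phi``) turns the system
into a pair of ODEs per grid node, advanced jointly with classical
fourth-order Runge-Kutta.  The quasi-steady drug field is refreshed once
per time step from the current density and held frozen across the four
RK4 stages, mirroring the staggered coupling of the underlying scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .diffusion import solve_sigma
from .grid import RadialGrid
from .observables import SimulationResult, Snapshot, mass_ratio
from .parameters import ModelParams

__all__ = ["State", "rhs", "rk4_step", "simulate", "CLAMP_TOL", "DEFAULT_DT", "DEFAULT_T_END"]

#: phi values in (-CLAMP_TOL, 0) are clamped to zero; anything below aborts.
CLAMP_TOL = 1e-12
DEFAULT_DT = 1e-3
DEFAULT_T_END = 10.0


@dataclass(frozen=True)
class State:
    """Simulation state at one instant.

    ``t`` is in units of the apoptotic cycle; ``phi`` is cell density
    relative to the initial density; ``U`` is the per-node cumulative drug
    uptake; ``sigma`` is the quasi-steady drug field consistent with ``phi``.
    """

    t: float
    phi: np.ndarray
    U: np.ndarray
    sigma: np.ndarray


def initial_state(grid: RadialGrid) -> State:
    """Homogeneous density phi = 1, zero uptake, and the matching drug field."""
    phi = np.ones(grid.n)
    sigma = solve_sigma(grid, phi).sigma
    return State(t=0.0, phi=phi, U=np.zeros(grid.n), sigma=sigma)


def rhs(
    phi: np.ndarray, U: np.ndarray, sigma: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise time derivatives (dphi/dt, dU/dt) = (phi*(alpha-U), sigma*phi)."""
    phi = np.asarray(phi, dtype=float)
    U = np.asarray(U, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (phi.shape == U.shape == sigma.shape):
        raise ValueError(
            f"shape mismatch: phi {phi.shape}, U {U.shape}, sigma {sigma.shape}"
        )
    return phi * (alpha - U), sigma * phi


def rk4_step(state: State, dt: float, alpha: float) -> State:
    """Advance (phi, U) one classical RK4 step with sigma held frozen.

    The continuous model preserves phi >= 0 (dphi/dt is proportional to
    phi), so only roundoff-scale undershoot is tolerated: values in
    (-1e-12, 0) are clamped to zero and anything more negative aborts.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    phi, U, sigma = state.phi, state.U, state.sigma

    k1p, k1u = rhs(phi, U, sigma, alpha)
    k2p, k2u = rhs(phi + 0.5 * dt * k1p, U + 0.5 * dt * k1u, sigma, alpha)
    k3p, k3u = rhs(phi + 0.5 * dt * k2p, U + 0.5 * dt * k2u, sigma, alpha)
    k4p, k4u = rhs(phi + dt * k3p, U + dt * k3u, sigma, alpha)

    phi_new = phi + (dt / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
    U_new = U + (dt / 6.0) * (k1u + 2 * k2u + 2 * k3u + k4u)

    if not (np.all(np.isfinite(phi_new)) and np.all(np.isfinite(U_new))):
        raise RuntimeError(
            f"time step too large: non-finite state at t={state.t:.4g}; "
            f"try dt <= {dt / 10:.3g}"
        )
    if np.any(phi_new < -CLAMP_TOL):
        raise RuntimeError(
            f"density undershoot below clamp tolerance at t={state.t:.4g} "
            f"(min phi = {phi_new.min():.3e}); reduce dt"
        )
    phi_new = np.maximum(phi_new, 0.0)
    return State(t=state.t + dt, phi=phi_new, U=U_new, sigma=sigma)


def simulate(
    mp: ModelParams,
    grid: RadialGrid,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    record_every: int | None = None,
    snapshot_times: tuple[float, ...] = (),
) -> SimulationResult:
    """Run the coupled quasi-steady-drug / cell-kill simulation.

    Each step re-solves the elliptic drug equation from the current
    density, then advances (phi, U) one RK4 step.  The viable-mass ratio
    f(t) is recorded every ``record_every`` steps (default: about 1000
    output rows) starting with f(0) = 1; optional field snapshots
    (r, phi, sigma) are taken at the recorded times nearest to
    ``snapshot_times``.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    n_steps = int(round(t_end / dt))
    if n_steps < 1:
        raise ValueError("t_end/dt must be at least 1")
    if record_every is None:
        record_every = max(1, n_steps // 1000)

    state = initial_state(grid)
    times = [0.0]
    f_values = [mass_ratio(grid, state.phi)]
    U_records = [state.U.copy()]
    snapshots: list[Snapshot] = []
    pending = sorted(snapshot_times)

    def maybe_snapshot(s: State) -> None:
        while pending and s.t >= pending[0] - 0.5 * dt * record_every:
            pending.pop(0)
            snapshots.append(Snapshot(t=s.t, r=grid.r.copy(), phi=s.phi.copy(), sigma=s.sigma.copy()))

    maybe_snapshot(state)
    for step in range(1, n_steps + 1):
        sigma = solve_sigma(grid, state.phi).sigma
        state = replace(state, sigma=sigma)
        state = rk4_step(state, dt, mp.alpha)
        if step % record_every == 0 or step == n_steps:
            times.append(state.t)
            f_values.append(mass_ratio(grid, state.phi))
            U_records.append(state.U.copy())
            maybe_snapshot(state)

    return SimulationResult(
        times=np.asarray(times),
        f=np.asarray(f_values),
        params=mp,
        snapshots=tuple(snapshots),
        U_series=np.asarray(U_records),
    )
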