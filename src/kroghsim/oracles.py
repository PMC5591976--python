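"""Closed-form reference solutions for verifying the numerical solvers.

Each oracle is evaluable at arbitrary (r, t) without running the
simulator, so the test suite (and the ``validate`` CLI subcommand) can
check the finite-difference and Runge-Kutta machinery against exact
analytic anchors:

* constant-density drug profile -> modified Bessel functions,
* frozen-drug point kill -> sech^2 / tanh pair,
* drug-free growth -> pure exponential.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import i0, i1, k0, k1

__all__ = ["bessel_sigma", "point_kill_phi", "exponential_growth", "run_validation"]


def bessel_sigma(a: float, R: float, c: float, r):
    """Exact quasi-steady drug profile for uniform cell density ``c``.

    Solves ``sigma'' + sigma'/r = c * sigma`` with ``sigma(a) = 1`` and
    ``sigma'(R) = 0``:

        sigma(r) = [K1(sR) I0(sr) + I1(sR) K0(sr)]
                 / [K1(sR) I0(sa) + I1(sR) K0(sa)],   s = sqrt(c).

    The boundary conditions follow from I0' = I1 and K0' = -K1.
    """
    if a >= R:
        raise ValueError(f"inner radius {a} must be smaller than outer radius {R}")
    if c <= 0:
        raise ValueError(f"density must be positive, got {c!r}")
    s = math.sqrt(c)
    r = np.asarray(r, dtype=float)
    denom = k1(s * R) * i0(s * a) + i1(s * R) * k0(s * a)
    return (k1(s * R) * i0(s * r) + i1(s * R) * k0(s * r)) / denom


def point_kill_phi(t):
    """Cell density and uptake under frozen unit drug and no growth.

    With sigma = 1 fixed and alpha = 0 the pair dU/dt = phi,
    dphi/dt = -phi*U integrates exactly (via phi = 1 - U^2/2) to

        phi(t) = sech^2(t / sqrt(2)),   U(t) = sqrt(2) * tanh(t / sqrt(2)),

    so the saturated uptake mu equals sqrt(2).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    x = t / math.sqrt(2.0)
    return 1.0 / np.cosh(x) ** 2, math.sqrt(2.0) * np.tanh(x)


def exponential_growth(alpha: float, t):
    """Drug-free density e^(alpha * t): exponential growth without treatment."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return np.exp(alpha * t)


def _self_check_residuals(dt: float = 1e-5) -> dict[str, float]:
    """Residuals of each oracle in its defining ODE via central differences."""
    t = np.linspace(dt, 3.0, 200)
    phi, U = point_kill_phi(t)
    dphi = (point_kill_phi(t + dt)[0] - point_kill_phi(t - dt)[0]) / (2 * dt)
    dU = (point_kill_phi(t + dt)[1] - point_kill_phi(t - dt)[1]) / (2 * dt)
    res_phi = float(np.max(np.abs(dphi + phi * U)))
    res_U = float(np.max(np.abs(dU - phi)))

    a, R, c = 0.102, 1.02, 1.0
    # Fourth-order central stencils with h = 1e-3: the profile's high
    # derivatives near the vessel wall make second-order differencing
    # truncation-limited above 1e-6 there.
    r = np.linspace(a + 0.01, R - 0.01, 200)
    h = 1e-3
    f = [bessel_sigma(a, R, c, r + k * h) for k in (-2, -1, 0, 1, 2)]
    d1 = (-f[4] + 8 * f[3] - 8 * f[1] + f[0]) / (12 * h)
    d2 = (-f[4] + 16 * f[3] - 30 * f[2] + 16 * f[1] - f[0]) / (12 * h**2)
    res_bessel = float(np.max(np.abs(d2 + d1 / r - c * f[2])))

    alpha = 0.3
    g = exponential_growth(alpha, t)
    dg = (exponential_growth(alpha, t + dt) - exponential_growth(alpha, t - dt)) / (2 * dt)
    res_exp = float(np.max(np.abs(dg - alpha * g)))
    return {
        "point_kill_dphi": res_phi,
        "point_kill_dU": res_U,
        "bessel_ode": res_bessel,
        "exponential_ode": res_exp,
    }


def run_validation(n_values: tuple[int, ...] = (101, 201, 401, 801)) -> list[dict]:
    """Run the oracle suite against the solvers; return pass/fail records.

    Checks (1) oracle self-consistency under numerical differentiation,
    (2) the elliptic solver against the Bessel profile with measured
    convergence order, and (3) RK4 against the point-kill closed form.
    """
    from .diffusion import solve_sigma
    from .dynamics import State, rk4_step
    from .grid import RadialGrid

    rows: list[dict] = []
    for name, res in _self_check_residuals().items():
        rows.append(
            {"check": f"oracle self-consistency: {name}", "error": res, "passed": res < 1e-6}
        )

    a, R = 0.102, 1.02
    errors = []
    for n in n_values:
        r = np.linspace(a, R, n)
        g = RadialGrid(r=r, r_inner=a, r_outer=R, h=(R - a) / (n - 1))
        num = solve_sigma(g, np.ones(n)).sigma
        errors.append(float(np.max(np.abs(num - bessel_sigma(a, R, 1.0, r)))))
    orders = [
        math.log2(errors[i] / errors[i + 1]) for i in range(len(errors) - 1)
    ]
    rows.append(
        {
            "check": f"elliptic solver vs Bessel profile (n={n_values[-1]})",
            "error": errors[-1],
            "passed": errors[-1] < 1e-3,
        }
    )
    rows.append(
        {
            "check": "elliptic solver spatial convergence order",
            "error": abs(min(orders) - 2.0),
            "passed": all(abs(o - 2.0) < 0.2 for o in orders),
        }
    )

    dt, t_end = 1e-3, 2.0
    sigma = np.ones(1)
    state = State(t=0.0, phi=np.ones(1), U=np.zeros(1), sigma=sigma)
    for _ in range(int(round(t_end / dt))):
        state = rk4_step(state, dt, alpha=0.0)
    phi_ref, U_ref = point_kill_phi(state.t)
    err = max(abs(float(state.phi[0]) - float(phi_ref)), abs(float(state.U[0]) - float(U_ref)))
    rows.append(
        {"check": "RK4 vs point-kill closed form (dt=1e-3)", "error": err, "passed": err < 1e-10}
    )
    return rows
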