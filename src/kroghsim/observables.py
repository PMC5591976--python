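"""Derived quantities: viable-mass ratio, death time, long-term regime.

The headline observable is the viable-mass ratio

    f(t) = M(t) / M(0) = (2*pi / V0) * int phi(r, t) * r dr,

the tumour mass relative to its initial mass over the annulus, with
``V0 = pi * (r_outer^2 - r_inner^2)``.  In the long-time limit the
cumulative uptake at a node saturates at a constant ``mu`` and the local
density behaves like ``exp((alpha - mu) * t)``: the tumour grows if
``alpha > mu``, decays if ``alpha < mu``, and is quiescent at balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import RadialGrid, annular_integral
from .parameters import ModelParams

__all__ = [
    "Snapshot",
    "SimulationResult",
    "Regime",
    "mass_ratio",
    "death_time",
    "classify_long_term",
    "saturated_uptake",
    "DEFAULT_EXTINCTION_THRESHOLD",
]

#: Fraction of the initial mass below which the tumour counts as dead.
DEFAULT_EXTINCTION_THRESHOLD = 1e-2

#: Relative tolerance for the alpha == mu quiescence comparison.
QUIESCENCE_RTOL = 1e-9


@dataclass(frozen=True)
class Snapshot:
    """Radial profiles of cell density and drug at one recorded time."""

    t: float
    r: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class SimulationResult:
    """Time series of the viable-mass ratio plus optional field snapshots.

    ``U_series`` holds the per-node cumulative drug uptake at the recorded
    times (shape ``(len(times), n_nodes)``) when the run recorded it.
    """

    times: np.ndarray
    f: np.ndarray
    params: ModelParams
    snapshots: tuple[Snapshot, ...] = field(default=())
    U_series: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.f):
            raise ValueError("times and f must have equal length")
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("time series must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class Regime:
    """Long-term fate of the tumour: 'growth', 'decay', or 'quiescence'."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ("growth", "decay", "quiescence"):
            raise ValueError(f"unknown regime label {self.label!r}")


def mass_ratio(grid: RadialGrid, phi: np.ndarray) -> float:
    """Viable-mass ratio (2*pi/V0) * int phi r dr; equals 1 for phi == 1."""
    return annular_integral(grid, phi) / grid.annulus_area


def death_time(
    result: SimulationResult, threshold: float = DEFAULT_EXTINCTION_THRESHOLD
) -> Optional[float]:
    """Earliest time at which f drops below ``threshold``.

    The crossing is linearly interpolated between the bracketing records;
    returns ``None`` if f never falls below the threshold within the run.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold!r}")
    below = np.nonzero(result.f < threshold)[0]
    if len(below) == 0:
        return None
    i = int(below[0])
    if i == 0:  # pragma: no cover - f[0] = 1 > threshold by construction
        return float(result.times[0])
    t0, t1 = result.times[i - 1], result.times[i]
    f0, f1 = result.f[i - 1], result.f[i]
    return float(t0 + (threshold - f0) * (t1 - t0) / (f1 - f0))


def classify_long_term(alpha: float, mu: float) -> Regime:
    """Classify the long-term regime from growth rate vs. saturated uptake.

    Growth if ``alpha > mu``, decay if ``alpha < mu``, quiescence when they
    balance to within a relative tolerance of 1e-9 (exact equality is
    measure-zero in floating point; the tolerance makes the classifier
    total).
    """
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu!r}")
    tol = QUIESCENCE_RTOL * max(abs(alpha), abs(mu), 1.0)
    if abs(alpha - mu) <= tol:
        return Regime("quiescence")
    return Regime("growth") if alpha > mu else Regime("decay")


def saturated_uptake(
    result: SimulationResult,
    node: int,
    *,
    rel_rate_tol: float = 1e-4,
) -> float:
    """Terminal cumulative uptake at one node, the estimate of mu.

    Parameters
    ----------
    node : int
        Grid node index at which to read the uptake history.
    rel_rate_tol : float
        Maximum allowed relative increase of U at the node over the final
        tenth of the run; a faster rise means the integral has not
        saturated and the terminal value would underestimate mu.

    Raises
    ------
    RuntimeError
        If the uptake at the node is still rising faster than
        ``rel_rate_tol`` (e.g. a strongly growing run).
    """
    if result.U_series is None:
        raise ValueError("result carries no uptake series")
    U_series = np.asarray(result.U_series, dtype=float)
    if U_series.shape[0] != len(result.times):
        raise ValueError("U_series rows must match result.times")
    u = U_series[:, node]
    tail_start = int(math.floor(0.9 * (len(u) - 1)))
    terminal = float(u[-1])
    rise = terminal - float(u[tail_start])
    if terminal > 0 and rise / terminal > rel_rate_tol:
        raise RuntimeError(
            f"uptake not saturated at node {node}: relative rise "
            f"{rise / terminal:.3e} over final tenth of the run exceeds "
            f"{rel_rate_tol:.1e}"
        )
    return terminal
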