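"""Quasi-steady drug transport on the annulus.

Drug diffusion equilibrates much faster than the cell-death timescale, so
the transport equation reduces to the elliptic problem

    (1/r) d/dr ( r dsigma/dr ) - phi * sigma = 0

with sigma = 1 at the vessel wall (Dirichlet) and zero radial flux at the
outer Krogh radius (Neumann).  The cylindrical Laplacian is discretized in
conservative (flux) form at second order and the resulting tridiagonal
system is solved directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .grid import RadialGrid

__all__ = ["DrugField", "solve_sigma"]


@dataclass(frozen=True)
class DrugField:
    """Dimensionless drug concentration on the grid nodes; bounded in [0, 1]."""

    sigma: np.ndarray


def solve_sigma(grid: RadialGrid, phi: np.ndarray) -> DrugField:
    """Solve the quasi-steady drug equation for a given cell-density field.

    Parameters
    ----------
    phi : array of shape (n,)
        Non-negative cell density at the grid nodes (the absorption field).

    Returns
    -------
    DrugField
        Drug concentration with ``sigma[0] == 1`` exactly and a discretely
        zero gradient at the outer node.

    Notes
    -----
    Interior nodes use the conservative stencil
    ``(1/r_i) [ r_{i+1/2} (s_{i+1}-s_i) - r_{i-1/2} (s_i-s_{i-1}) ] / h^2``.
    The outer Neumann condition is imposed through the second-order ghost
    relation ``s_{n} = s_{n-2}``, which keeps the whole scheme order 2.
    For ``phi >= 0`` the operator is an irreducibly diagonally dominant
    M-matrix, so the system is nonsingular and the discrete solution obeys
    the maximum principle ``0 <= sigma <= 1``.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (grid.n,):
        raise ValueError(f"phi has shape {phi.shape}, expected ({grid.n},)")
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative elementwise")

    n = grid.n
    h = grid.h
    r = grid.r
    r_half_plus = r + 0.5 * h   # r_{i+1/2}
    r_half_minus = r - 0.5 * h  # r_{i-1/2}

    # The Dirichlet unknown sigma_0 = 1 is eliminated: solve the (n-1)
    # tridiagonal system for nodes 1..n-1, moving the known boundary value
    # to the right-hand side.  Banded storage for solve_banded((1, 1), ...):
    # row 0 = superdiag, row 1 = diag, row 2 = subdiag.
    m = n - 1
    ab = np.zeros((3, m))
    rhs = np.zeros(m)

    i = np.arange(1, n - 1)
    sub = r_half_minus[i] / (r[i] * h**2)
    sup = r_half_plus[i] / (r[i] * h**2)
    k = i - 1  # position within the reduced system
    ab[1, k] = -(sub + sup) - phi[i]
    ab[0, k + 1] = sup
    ab[2, k[1:] - 1] = sub[1:]
    rhs[0] = -sub[0] * 1.0  # boundary contribution from sigma_0 = 1

    # Outer node with ghost s_n = s_{n-2}: both flux terms couple to s_{n-2}.
    j = n - 1
    coupling = (r_half_plus[j] + r_half_minus[j]) / (r[j] * h**2)  # = 2/h^2
    ab[1, m - 1] = -coupling - phi[j]
    ab[2, m - 2] = coupling

    try:
        interior = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur for phi >= 0
        raise RuntimeError(
            "quasi-steady drug solve failed: tridiagonal system singular "
            f"(n={n}, h={h:.3e}, phi range [{phi.min():.3e}, {phi.max():.3e}])"
        ) from exc
    if not np.all(np.isfinite(interior)):  # pragma: no cover
        raise RuntimeError("quasi-steady drug solve produced non-finite values")
    sigma = np.empty(n)
    sigma[0] = 1.0
    sigma[1:] = interior
    return DrugField(sigma=sigma)
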