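"""Parameter sets and nondimensionalization.

The simulator works entirely in dimensionless variables: lengths are
measured in units of the drug diffusion length ``L = sqrt(D / (phi0 *
lambda_u))`` and times in units of the apoptotic-cycle timescale ``T =
(lambda_k * lambda_u * phi0 * sigma0) ** -0.5``.  Dimensional inputs exist
only at this boundary; every other module consumes :class:`ModelParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "nondimensionalize",
    "validate",
]


@dataclass(frozen=True)
class DimensionalParams:
    """Physical constants of the dimensional drug-transport / cell-kill model.

    Parameters
    ----------
    D : float
        Drug diffusivity (length^2 / time).
    lambda_u : float
        Cellular uptake rate of drug per volume (1 / (density * time)).
    lambda_k : float
        Death rate of tumour cells per unit cumulative drug concentration.
        Units are only constrained through the product
        ``lambda_k * lambda_u * phi0 * sigma0`` having units 1 / time^2.
    sigma0 : float
        Drug concentration held at the vessel wall (concentration).
    phi0 : float
        Initial (homogeneous) tumour cell density (density).
    alpha : float
        Cell growth rate (1 / time); zero means no proliferation.
    rb : float
        Blood vessel radius (length).
    """

    D: float
    lambda_u: float
    lambda_k: float
    sigma0: float
    phi0: float
    alpha: float
    rb: float

    def __post_init__(self) -> None:
        for name in ("D", "lambda_u", "lambda_k", "sigma0", "phi0", "rb"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not math.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha!r}")

    @property
    def time_scale(self) -> float:
        """Apoptotic-cycle timescale T = (lambda_k lambda_u phi0 sigma0)^(-1/2)."""
        return (self.lambda_k * self.lambda_u * self.phi0 * self.sigma0) ** -0.5

    @property
    def length_scale(self) -> float:
        """Drug diffusion length L = sqrt(D / (phi0 lambda_u))."""
        return math.sqrt(self.D / (self.phi0 * self.lambda_u))


@dataclass(frozen=True)
class ModelParams:
    """The three dimensionless knobs that fully determine a simulation.

    Parameters
    ----------
    alpha : float
        Dimensionless growth rate (growth per apoptotic cycle).
    rb_over_L : float
        Vessel radius in units of the diffusion length.
    bvf : float
        Blood volume fraction, the ratio of blood volume to tumour volume;
        strictly between 0 and 1.  Sets the outer no-flux radius
        ``rb_over_L / sqrt(bvf)`` of the tissue annulus served by one vessel.
    """

    alpha: float
    rb_over_L: float
    bvf: float

    def __post_init__(self) -> None:
        validate(self)

    @property
    def outer_radius(self) -> float:
        """Dimensionless radius of the tissue cylinder supported by the vessel."""
        return self.rb_over_L / math.sqrt(self.bvf)


def validate(mp: ModelParams) -> ModelParams:
    """Check :class:`ModelParams` invariants, returning ``mp`` unchanged.

    Raises
    ------
    ValueError
        If any invariant fails, naming the offending field.
    """
    if not math.isfinite(mp.bvf) or not (0.0 < mp.bvf < 1.0):
        raise ValueError("BVF must lie strictly between 0 and 1")
    if not math.isfinite(mp.rb_over_L) or mp.rb_over_L <= 0:
        raise ValueError(f"rb_over_L must be strictly positive, got {mp.rb_over_L!r}")
    if not math.isfinite(mp.alpha) or mp.alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {mp.alpha!r}")
    return mp


def nondimensionalize(p: DimensionalParams, bvf: float) -> tuple[ModelParams, float, float]:
    """Convert dimensional constants to the dimensionless parameter set.

    The blood volume fraction is a tissue property independent of the seven
    physical constants and must be supplied alongside them.

    Returns
    -------
    (ModelParams, T, L)
        The dimensionless parameters together with the time scale ``T``
        (apoptotic cycle) and length scale ``L`` (diffusion length).
    """
    T = p.time_scale
    L = p.length_scale
    mp = ModelParams(alpha=p.alpha * T, rb_over_L=p.rb / L, bvf=bvf)
    return mp, T, L
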