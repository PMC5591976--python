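# Methods

## Model and assumptions

The simulator treats one blood vessel and the coaxial annulus of tumour
tissue it supplies (Krogh-type cylinder, no exchange across the outer
boundary). Four modelling assumptions define the scope:

1. **Quasi-steady drug transport.** Drug diffusion equilibrates much
   faster than cells die, so the transport equation is solved as an
   elliptic problem, ∇²σ − φσ = 0, afresh at every time step with the
   current cell density as the absorption field. Time-dependent
   transport, perfusion/advection, and multi-vessel geometries are out
   of scope.
2. **Continuous delivery.** The drug concentration at the vessel wall is
   held at its dimensionless value 1 for all time. Bolus or cyclic
   schedules are not implemented.
3. **Cumulative-uptake killing.** The per-cell death rate is
   proportional to the history integral U(r, t) = ∫₀ᵗ σφ dτ — damage
   accumulates, it is not an instantaneous-concentration effect. This is
   the only death mechanism.
4. **Exponential proliferation.** Growth is a constant per-capita rate α;
   density-dependent (logistic/Gompertz) laws are out of scope.

All internal computation is dimensionless. Dimensional constants enter
only through `parameters.nondimensionalize`, which derives the apoptotic
cycle T = (λ_kλ_uφ₀σ₀)^(−1/2) and diffusion length L = √(D/(φ₀λ_u)).
Only the product λ_kλ_uφ₀σ₀ is constrained to have units 1/time², so no
specific unit is imposed on λ_k alone. The blood volume fraction is an
independent tissue property, supplied alongside the physical constants
rather than derived from them.

## Parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| `alpha` | growth rate per apoptotic cycle | — (user) | the biological knob under study |
| `rb_over_L` | vessel radius / diffusion length | — (user) | small values = deep drug penetration |
| `bvf` | blood volume fraction ∈ (0, 1) | — (user) | sets outer radius r_b/(L√BVF); high = well vascularized |
| `n_r` | radial nodes | 401 | resolves radius ratios up to 10 at second order (convergence demonstrated in tests) |
| `dt` | RK4 step (cycles) | 1e-3 | time-stepping error (O(dt⁴)) far below spatial error at default n_r |
| `t_end` | horizon (cycles) | 10 | the reference tumours all reach extinction well within it |
| `threshold` | extinction cutoff on f | 1e-2 | operationalizes "all cells die"; with the ceiling-in-cycles convention the reference run gives 6 cycles; configurable and recorded in output metadata |
| `record_every` | output cadence | ≈1000 rows | enough resolution to interpolate crossings |

## Numerical scheme

**Spatial discretization.** Uniform mesh on [r_inner, r_outer]. The
cylindrical Laplacian uses the conservative flux form
(1/r_i)[r_{i+1/2}(σ_{i+1}−σ_i) − r_{i−1/2}(σ_i−σ_{i−1})]/h², which
preserves the flux structure and is second-order. The vessel-wall
Dirichlet value is eliminated from the linear system (so σ[0] = 1 holds
exactly); the outer zero-flux condition is imposed through the
second-order ghost relation σ_n = σ_{n−2}. For φ ≥ 0 the operator is an
irreducibly diagonally dominant M-matrix: the direct tridiagonal solve
cannot fail and the discrete solution inherits the maximum principle
0 ≤ σ ≤ 1. There are no iterative-solver tolerances.

**Quadrature.** Mass integrals use the composite trapezoid rule on
2π∫φ r dr. For constant φ the integrand is linear, so f(0) = 1 is exact
rather than approximate.

**Time integration.** The history integral is carried as a state
variable (dU/dt = σφ) — an exact reformulation that avoids re-quadrature
of the past and makes classical RK4 applicable to the joint (φ, U)
system. The drug field is refreshed once per time step and held frozen
across the four RK4 stages, a first-order splitting of the coupling; a
regression test compares against per-stage refreshing and bounds the
difference below the spatial error at default resolution. RK4 alone
converges at fourth order (verified against the closed-form kill
solution).

**Degenerate inputs and tie-breaks.** φ values in (−1e-12, 0) after a
step are clamped to zero (the continuous model preserves positivity;
only roundoff-scale undershoot is tolerated — anything larger aborts
with a suggested smaller dt). Extinction times are linearly interpolated
between the bracketing records; a run that never crosses the threshold
reports "none" rather than the horizon. The growth-vs-decay classifier
treats |α − μ| ≤ 1e-9·max(α, μ, 1) as quiescence, since exact equality
is measure-zero in floating point.

**Long-term regime in sweep summaries.** The saturated uptake μ varies
with radius, and the model itself leaves the spatial interpretation
open. The sweep summary classifies each run using the terminal uptake at
the *outermost* node: that node receives the least drug, so its uptake
is the binding constraint on whether any tissue survives. Per-node
values are available via `saturated_uptake`, which refuses to report a
value when the uptake is still rising by more than a relative 1e-4 over
the final tenth of the run.

## Verification strategy

No closed form exists for the fully coupled problem, so verification
rests on three analytic anchors plus structural properties:

- **Elliptic solver:** for uniform density the drug profile is a ratio
  of modified Bessel functions (I₀, I₁, K₀, K₁); the solver matches it
  to better than 1e-4 at 1001 nodes with measured convergence order 2.
- **Time integrator:** with the drug frozen at 1 and no growth, the
  (φ, U) pair integrates exactly to φ = sech²(t/√2), U = √2·tanh(t/√2);
  RK4 matches with fourth-order error and the terminal uptake gives
  μ = √2.
- **Growth limit:** with no drug, the simulator reproduces e^(αt).
- **Properties:** σ bounded in [0, 1] and monotone in both radius and
  absorption (maximum principle); U non-decreasing everywhere; f(0) = 1
  exactly; death times ordered monotonically in α, BVF, and r_b/L
  across the default sweep.

Each oracle is additionally self-validated against its defining ODE by
numerical differentiation (fourth-order stencils, residual < 1e-6 —
second-order differencing is truncation-limited near the vessel wall
where the Bessel profile is steep). The oracles ship in the installed
package so users can re-run the whole validation (`kroghsim validate`)
after modifying the numerics.

## Problem sizes

Default production resolution is 401 radial nodes and dt = 1e-3 over a
10-cycle horizon (10⁴ elliptic solves per run, a few seconds each run).
The test suite runs plumbing checks at reduced resolution (64–101 nodes,
dt up to 0.02) and reserves full resolution for the end-to-end checks,
which share one 12-run sweep per session.

## Known limitations

- Continuous delivery only; the wall concentration cannot vary in time.
- One vessel, cylindrical symmetry, uniform mesh: no vascular networks,
  no adaptive refinement for extreme radius ratios (r_outer/r_inner ≫ 10
  would want more nodes).
- The quasi-steady approximation is hard-wired; regimes where drug
  transport is as slow as cell death are outside the model's validity.
- The critical growth rate α* above which treatment fails is not
  root-found automatically; it can be bracketed manually with `sweep`.
- No fitting of the dimensional constants to experimental data.
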