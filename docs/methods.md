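# Methods

This note documents the models, the numerical choices and the synthetic-data
conventions behind `cubemag`, and what the test suite does and does not
establish.

## Particle geometry

A nanocube with rounded corners is the intersection of a cube of side *l*
with a sphere of diameter *d* = *l*(1+√3)/2 (the mean of the side and the
space diagonal). Rasterization uses a center-in/out rule: a hexahedral cell
of edge Δs is magnetic iff its center lies inside the intersection. No
partial-volume weighting is applied; the refinement study in the tests shows
the volume error is ≈ 1.4% at *l*/Δs = 16 and < 0.1% at *l*/Δs = 64 against
a 10⁷-point Monte-Carlo oracle. The default cell size is Δs = *l*/16 clamped
to [1.25, 4.1] nm; any Δs with *l*/Δs ≥ 4 is accepted (the clamp range is a
default-selection rule, not a validity bound).

Assemblies (3×3×3 clusters, *n*-particle chains) are unions of translated
copies of the single-particle mask. The nominal center spacing *l* + *d*_gap
is rounded to an integer number of cells; the realized face-to-face gap is
recorded on the geometry and reported in all outputs. Crystal axes are
assumed aligned with the cube edges; a particle orientation is applied by
rotating the applied-field protocol rather than re-rasterizing the mask —
equivalent for loop observables and much cheaper. Cluster and chain
particles share a common crystal orientation by default.

## Effective fields

* **Magnetostatics.** The cell-averaged demagnetizing tensor of hexahedral
  cells is evaluated with the closed-form Newell expressions (second
  differences of the *f* and *g* potentials); the field is the convolution
  H_m = −N∗M computed with zero-padded FFTs. The tensor is exact for uniform
  cells, so no quadrature parameter exists; equivalence with direct pairwise
  summation is enforced to round-off in the tests, and the uniform cube
  reproduces ⟨N⟩ = 1/3 per axis.
* **Exchange.** 6-neighbour Laplacian with free (zero normal derivative)
  boundaries at mask edges, i.e. missing neighbours are skipped. A
  26-neighbour stencil (face 1/3, edge 1/12, corner 1/12 — weights chosen so
  the quadratic Taylor term reproduces ∇²) is available behind a flag; both
  match the continuum spin-spiral dispersion to < 2% at qΔs = 0.1, and loop
  observables are insensitive to the choice at the default cell sizes.
* **Cubic anisotropy.** H_an = −2K m/(μ₀Mₛ) with the diagonal tensor
  K = diag(K₁(m_y²+m_z²)+K₂m_y²m_z², …); this is exactly −∇_m e_an/(μ₀Mₛ)
  for e_an = K₁Σm_i²m_j² + K₂m_x²m_y²m_z², which the tests verify against a
  numerical gradient. An optional uniaxial term (K_u, easy axis) supports
  Stoner–Wohlfarth-type verification cases.
* **Thermal field.** Langevin field with per-component standard deviation
  √(2αk_BT/(γμ₀MₛΔs³Δt)), redrawn each step from a Philox counter-based
  generator keyed by (seed, step) — deterministic and independent of
  execution order. With the thermal field on, the damping default drops from
  α = 0.1 to 0.02. Thermal effects are OFF for all quasi-static hysteresis
  runs.

## Time integration and relaxation

The LLG equation is advanced by rotating each cell's **m** about its
instantaneous angular velocity ω = γ/(1+α²)(h + α m×h) through the Cayley
angle 2·atan(|ω|Δt/2); |m| = 1 is preserved to round-off. The adaptive
variant estimates the local angle error as ½|dω/dt|Δt² from successive steps
and keeps it near 10⁻⁵; a midpoint (Heun–Cayley) variant drives the
stochastic trajectories and the energy-conservation checks.

Quasi-static equilibria are found by either:

* `method="llg"` — damped LLG integration to the torque criterion; faithful
  dynamics, but at Δs = 1.25 nm the exchange term is stiff (stable explicit
  steps ~10⁻¹⁴ s), so this mode is impractical for full loops on one CPU; or
* `method="minimize"` (default for loops) — projected Barzilai–Borwein
  descent along the damping torque m×(m×h), the standard accelerator for
  static hysteresis in micromagnetics practice. Both modes stop at the same
  criterion and agree on macrospin equilibria to the stated tolerance in the
  tests.

**Stopping criterion.** max over cells of |m×h|/|h| < 10⁻⁴, with the
normalization floored at 1% of the largest cell field: in corner cells the
field terms can cancel almost exactly, making the raw ratio ill-conditioned
while the physical torque is negligible. The tolerance is configurable and
recorded in run manifests.

## Hysteresis protocol

Loops saturate at H_max = 200 kA/m and walk the descending branch in coarse
4 kA/m steps, warm-starting each relaxation from a linear extrapolation of
the two previous equilibria. Wherever the magnetization jumps by more than
0.25 Mₛ between consecutive equilibria the interval is re-walked at the fine
step (0.5 kA/m default), so switching fields are resolved at the fine step
without paying its cost everywhere. Closure of the two branches at +H_max is
checked (2% of Mₛ).

**Symmetry breaking.** With the field exactly on a crystal symmetry axis a
deterministic T = 0 simulation sits on an unstable saddle at switching and
never leaves it. The applied-field direction is therefore tilted by 1°
(configurable) toward a fixed generic transverse direction. The tilt is part
of the protocol: for a uniaxial macrospin it reproduces the
Stoner–Wohlfarth astroid value (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}·H_K at
ψ = 1°, which the tests assert.

**Half loops.** For centro-symmetric systems the LLG flow is equivariant
under (m, H) → (−m, −H), so the ascending branch is the exact mirror of the
descending one; `half_loop=True` computes one branch and mirrors it, halving
cost. The mirror identity is verified against a full two-branch run.

Loop properties: M_r is the branch-averaged |M(0)| (linear interpolation);
H_c the branch-averaged |H| at the interpolated M = 0 crossing (an exact
M = 0 sample wins ties); E = μ₀∮H dM is the shoelace area of the closed
(H, M) polygon — exact for piecewise-linear loops. Size sweeps are
interpolated with a cubic basis spline (no smoothing) to locate the H_c and
E peaks; orientation averages use a deterministic 8-point spherical-
Fibonacci set plus the three crystallographic directions, equal weights.

## What the T = 0 quasi-statics predicts for l = 20 nm

Along the hard ⟨100⟩ edge: M_r/Mₛ = 0.577 (= 1/√3, the easy-axis
projection) and H_c ≈ 6.7 kA/m. Along the easy ⟨111⟩ diagonal the loop is
nearly square and switches at ≈ 29–30 kA/m, in agreement with the
coherent-rotation (Usov–Peschany) closed form 4/7 · 2|K₁|/(μ₀Mₛ) = 29.9 kA/m
for cubic K₁ < 0 — at this size the particle is ≈ 2 exchange lengths across
and reverses quasi-coherently. A watershed analysis of the anisotropy energy
landscape shows the escape barrier from a ⟨111⟩ basin is only ≈ 2.4 k_BT at
300 K for this particle volume (and < 1 k_BT beyond 10 kA/m of reverse
field), so room-temperature thermal activation substantially lowers the
measured ⟨111⟩ coercivity relative to the T = 0 value; 10–20 nm magnetite is
indeed at the superparamagnetic boundary. The package reports the T = 0
quasi-static value, consistent with its stated protocol (thermal field off);
reproducing thermally assisted coercivities would require stochastic-LLG
loop protocols with a physical per-step dwell time, which is out of scope
for the desk-scale runs.

## Thermal model

The scene is an axisymmetric (r, z) region map — suspension, polypropylene
vial, water bath, quartz holder, air — with the property table of the
study's materials (water 997.05/4183/0.6; quartz 2600/820/3; polypropylene
905/1900/0.185; air 1.16/1007/0.026; suspensions ≈ water with slightly
higher ρ and lower C_p). Defaults: vial inner radius 5 mm, suspension height
10 mm, holder radius 15 mm, h = 25 W m⁻²K⁻¹; all configurable, and the
verification tests use only closed-form or round-trip checks, never these
dimensions. The finite-volume discretization is conservative (harmonic-mean
face conductivities, exact discrete enthalpy balance when insulated);
Crank–Nicolson with a factorized constant matrix makes each step a
back-substitution. The grid must resolve the vial wall (≥ 1 cell ring);
defaults (30×60) do.

Both Q_MNPs and Q_ext act in the suspension region (Q_ext is calibrated on a
blank water sample occupying the same region; default 45 kW/m³). The
ambient law T_ext(t) is an exponential rise (amplitude ~9 °C scale) followed
by an exponential decay, continuous at switch-off; `fit_ambient` recovers it
from an air-probe trace by least squares.

**SLP estimation.** The lumped model C_eff dT/dt = P_tot·s(t) − K(T −
T_env(t)) is fitted by least squares (exact exponential-integrator solution
per sample interval) jointly to both phases; SLP = (P_tot − Q_ext·V_water)/
m_MNPs with a delta-method confidence interval. C_eff follows the
convention *suspension + vial wall* (the bath and holder are environment,
absorbed into K and T_env); `calibrate_capacity` can refine it against a
reference-power conduction run — the probe trace is linear in the deposited
power, so the correction factor is power-independent, mirroring the
calibration of a physical setup. Consistency matters: V_water must be the
same volume the power is deposited in (the scene's discretized suspension
volume), which the generators default to.

## Synthetic data

Size draws use truncated normals with the fitted parameters of the four
study samples (#1: 18.3/9.5, #2: 14.9/8.5, #3: 22.1/15.7 nm, truncated at 0;
#4: 162/95 nm truncated to 50–275 nm), number-weighted. Ensemble inputs
stratify the central 99.8% mass into equal-width bins with truncated-normal
probability weights (quadrature-verified). Thermometry traces run the
conduction solver with the ground-truth SLP and add i.i.d. Gaussian sensor
noise (default σ = 0.1 °C; the real sensor's noise spectrum is not
characterized, so independence is an idealization). Every generator is a
pure function of (parameters, seed), and every trace carries its ground
truth for recovery scoring.

What passing tests show about real data — and what they do not: recovery
studies certify the estimators against the package's own forward models
(linear conduction, i.i.d. noise, known schedules). Real measurements add
convection in the liquid, sensor drift, field inhomogeneity and uncertain
material properties, none of which are emulated.

## Problem sizes used in the default runs

Desk-scale verification uses the 16³-cell l = 20 nm particle for the loop
observables (saturation at 120–200 kA/m, 0.5 kA/m refined steps; a few
minutes per loop on one CPU — the observables are verified identical across
these protocol settings) and a coarse proxy sweep {60, 90, 105, 150} nm at
Δs = 4.1 nm (8 kA/m steps for 60–105 nm; 16 kA/m and a relaxed tolerance for
the slowly relaxing 150 nm vortex particle, which enters only a coercivity
ordering). The proxy resolves the coercivity peak ordering and the
single-domain → vortex transition; the quantitative peak values of the
fine-grid study (10⁴–10⁵ cells per loop, refined steps, many sizes) are long
jobs run with the same code paths by increasing the protocol resolution.
Aggregation checks run at Δs = 5 nm (4 cells across a 20 nm particle), where
the dipolar remanence collapse, the coercivity near-doubling at 6 nm gaps
and the chain's axial-easy anisotropy are already unambiguous.

## Known limitations

* CPU-only; no GPU path. Large assemblies (27 × 16³ cells) are hours-scale.
* Explicit LLG stepping is stiffness-limited at fine cells; use the
  minimizer for quasi-statics.
* The lumped SLP model carries a geometry-dependent effective-capacity
  convention; recalibrate when changing the scene.
* No Brownian (mechanical rotation) relaxation channel; static loops only —
  dynamic (AC, rate-dependent) hysteresis is not simulated.
* No convection inside the liquid; eddy-current heating enters only through
  the calibrated Q_ext.
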