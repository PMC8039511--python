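# Methods

## Model overview

`gravipin` couples four stages of the gravitropic signalling pathway of
a shoot-like organ, each with explicit assumptions:

1. **Statolith pile geometry.** The statocyte cross-section is a W × H
   rectangle; the sedimented statolith pile is treated as an effective
   liquid of conserved cross-section area W·H_stato whose free surface
   is horizontal in the lab frame. Repositioning after a tilt is
   instantaneous (sedimentation is much faster than PIN turnover at
   Earth-like gravity), and the pile's granular agitation is neglected.
   Geometry is two-dimensional: all "surface areas" are edge lengths per
   unit depth, consistent with the closed-form response law depending on
   H, W, H_stato only.

2. **PIN trafficking.** PIN carriers exchange between the membrane and a
   well-mixed cytoplasmic pool by endocytosis (rate k_off,i) and
   exocytosis (volumetric rate κ_i = k_on,i/W), with different rate
   pairs for membrane in contact with statoliths (class 1) and free
   membrane (class 0). Total PIN is conserved (no synthesis or
   degradation on the hour timescale) and PIN diffusion within the
   membrane is neglected. Two groups control the behaviour: the
   coupling ratio R = κ₁k_off,0/(κ₀k_off,1) (steady concentration
   contrast between contacted and free membrane) and the pool number
   P = k_off,1/κ₁ (P ≪ 1: limiting pool, all PIN membrane-bound; P ≫ 1:
   infinite pool).

3. **Auxin transport.** The tissue is a 1D row of N identical cells with
   impermeable organ faces. The discrete quasi-steady-wall hopping model
   is itself the method-of-lines discretization used for transients; its
   continuum limit is advection–diffusion with D = W·P̄/2 fixed and
   v set by the PIN left/right asymmetry, summarized by the Peclet
   number Pe = 2R_organ·v/D (instantaneous, time-dependent). Auxin is
   neither created nor degraded, and growth dilution is neglected.

4. **Growth and curvature.** Local growth rate is proportional to local
   auxin concentration, so the dimensionless response
   Δ̃ = (c_bottom − c_top)/(2c_mean) equals the normalized curvature
   rate: dC/dt = Δ̃/(R_organ·τ_g). Tip angle is reported as
   L_gz·C in degrees and is meaningful only up to the assumed
   growth-zone length L_gz (the organ-scale data it emulates fix only
   the time dependence, not this prefactor).

## Parameters, units, defaults

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| W, H, H_stato | statocyte width/height, pile height (statolith diameters d) | 10, 25, 4 | wheat-coleoptile statocyte aspect ratios |
| binding mode | walls that bind PIN | lateral | the only regime producing a concave sine-like curve |
| R | statolith–PIN coupling | 25 | steady-response fit; shape saturates for larger R |
| P | pool number | 1e-4 | deep limiting pool; response shape is P-independent below ~1e-2 |
| τ_PIN | slow PIN turnover time | 13 min | dose-response fit; the pathway's memory time |
| A | PIN/total-efflux conductance ratio × N | 1.3 | amplitude of the steady-response fit |
| τ_aux | diffusive auxin relaxation time | τ_PIN/2000 | transport is fast; only the ratio to τ_PIN matters when ≪ 1 |
| N | cells across the organ | 100 | discretization error O(1/N²) ≈ 10⁻⁴ on Δ̃ |
| R_organ, τ_g, L_gz | organ radius, growth time, growth zone | 0.5 mm, 1200 min, 10 mm | representative coleoptile values; pure output scaling |

Times are minutes everywhere in the API; angles are degrees at
interfaces and radians internally. `relaxation_time` alone returns
seconds (it reproduces a back-of-envelope estimate in micrometre/second
units).

The reduced parametrization (R, P, τ_PIN) anchors the four rates with
**equal endocytosis rates** k_off,0 = k_off,1 = 1/τ_PIN, i.e. the
contact bias acts through exocytosis. In the limiting pool this makes
the slow eigen-time exactly τ_PIN and drives the fast time
τ₁ = S·P·τ_PIN/(S₀/R + S₁) to zero with P, matching the
τ₁/τ_PIN ≈ 0 regime the transient analyses assume. The endocytosis-
biased alternative (k_off,0 ≫ k_off,1, equal k_on) is available through
raw rates; its slow time is controlled by the *fastest* detachment rate
(τ₂ ≈ (1 + S₀/S₁)/k_off,0) because the limiting pool couples the two
classes.

## Membrane bookkeeping across inclination switches (design choice)

The two-class ODE alone does not say what happens to a membrane patch
whose contact class changes when the pile moves. Two schemes are
implemented:

* **`patch` (default, locally mass-conserving).** Every membrane patch
  keeps its local PIN concentration at a switch and subsequently relaxes
  with its new class's rates. Because coverage intervals are contiguous,
  patches are tracked *exactly* as history intervals (a handful of
  compartments), propagated in closed form through an eigendecomposition
  of the affine compartment system — the system matrix is similar to a
  symmetric one via the scaling diag(√(κ_b/L_b)), so the eigenbasis is
  orthogonal and the propagation is robust at any stiffness. In the
  limiting-pool, equal-k_off case this scheme yields the exact
  single-exponential memory law Pe(t) = Pe_steady(1 − e^{−t/τ_PIN}),
  zero initial asymmetry after a tilt (left and right walls start with
  identical PIN profiles), the t^{3/2} early-time gradient, and a
  dose-response crossover at τ_PIN.

* **`pooled` (literal class-averaged reading).** The two class
  concentrations u₀, u₁ are carried continuously across the switch and
  the free pool absorbs the jump in membrane totals. Analysis of the
  fast mode shows this scheme cannot produce a memory: the fast
  eigenvector (κ₀, κ₁) is parallel to the steady ray (1, R), so after a
  tilt the state relaxes to the new steady asymmetry within the fast
  time τ₁ (and the pool transiently goes significantly negative). It is
  retained for comparison and is exercised by the test suite, but it is
  not the default because it suppresses the memory behaviour the model
  exists to describe.

Both schemes agree on all steady-state quantities.

## Numerical choices

* **Pile level.** The free-surface level λ solves area(λ) = W·H_stato by
  Brent root-finding on the monotone area function (shapely polygon
  clipping; xtol 10⁻¹² · max(W, H)). Per-face covered intervals follow
  analytically from the linear depth potential, so θ = 90° needs no
  tangent anywhere. Negative θ is the exact mirror image.
* **Transport integration.** The auxin deviation δ = c/c_mean − 1 is
  integrated (method of lines, N cells) with an implicit solver and the
  analytic Jacobian T₀ + Pe(t)·T₁: BDF for phases comparable to τ_aux,
  LSODA for long quasi-steady stretches, with the first step forced
  inside the auxin boundary layer. Default rtol 10⁻⁸, atol 10⁻¹³ (the
  early-time power-law analyses pass 10⁻¹⁰/10⁻¹⁸ since Δ̃ reaches 10⁻⁷
  there). The PIN subsystem is never integrated numerically inside
  `simulate`: it is linear per phase and propagated exactly.
* **Discrete response convention.** The closed-form Δ̃ uses organ-face
  concentrations; with cell-centered unknowns the boundary-cell values
  carry an O(1/N) bias (≈1% at N = 100, Pe = 1), so `relative_gradient`
  linearly extrapolates the two outermost cells to the faces (O(1/N²);
  ≈10⁻⁴ at N = 100). The raw boundary-cell convention remains available
  as `mode="cell"`.
* **Dose-response maximum.** Δ̃ is maximized over a dense output grid
  with a log-spaced head after each switch; the maximum sits within
  O(τ_aux) after stimulus end, so the post-stimulus window 60·τ_aux
  suffices.
* **Sine-law fit.** A enters linearly, so the fit profiles R on a
  200-point log grid with the conditional  solved in closed form, then
  polishes with bounded multi-start least squares (6 starts) in
  (log₁₀R, A). When the residual at the upper R bound matches the
  optimum within 10⁻³ (relative), the result is flagged as a plateau and
  the lower plateau edge is reported instead of pretending R is
  identified.
* **Memory-time fit.** With τ_aux/τ_PIN fixed (default 1/2000) the
  transient model depends on duration only through ΔT/τ_PIN, so the fit
  interpolates one cached simulated master curve in log ΔT/τ_PIN and
  optionally polishes against direct simulations. Data whose smallest
  duration exceeds ~3·τ̂ lie entirely on the saturation plateau and are
  flagged unidentifiable.
* **Degenerate inputs.** Zero-length membrane segments are dropped at
  switches; a repeated PIN eigenvalue is handled by the symmetrized
  eigendecomposition; Pe values implying a negative one-sided
  permeability (|Pe| > 2N) raise instead of silently breaking
  positivity.

## What the synthetic data do and do not emulate

The generators draw responses from the model's own closed-form
(steady) or simulated (transient) curves plus additive homoscedastic
Gaussian noise with σ = 0.05, a scatter comparable to coleoptile
response measurements. They reproduce the *conditions* of such
experiments — angle sweeps over [0°, 180°], log-spaced stimulus
durations of 1–120 min — but not their error structure (replicate
plant-to-plant variability is neither homoscedastic nor Gaussian, and
real protocols bin by angle), nor any physiology outside the model
(reaction delay, proprioception, sedimentation dynamics). Passing
recovery tests therefore demonstrates the identifiability and
correctness of the estimation machinery under the stated noise model,
not the validity of the model for any particular organism.

## Known limitations

* The observed reaction delay (~10 min between stimulus and first
  visible bending) is explicitly outside the model; predicted responses
  start at t = 0.
* Gravity intensity does not enter anywhere: sedimentation is
  instantaneous and the statocyte is a pure inclination sensor. Effects
  of statolith agitation, saltation, or slow repositioning are out of
  scope.
* One-dimensional transverse transport in a homogeneous tissue; no
  longitudinal gradients, no endodermis-restricted statocyte ring, no
  auxin production/decay. Feedback of organ reorientation on θ is off
  by default; ``simulate(..., curvature_feedback=True)`` closes the
  loop approximately (piecewise-constant θ updates every
  ``feedback_dt`` minutes) for exploration only, and no reported
  quantity uses it.
* Behaviour for 90° < θ < 180° follows the same liquid-pile rule as
  below 90°; the printed closed form it extends only covers θ ≤ 90°, so
  beyond 90° the law is the package's geometric continuation (it is
  antisymmetric and vanishes at 180° as required).
* Tip angle is reported up to the growth-zone-length prefactor.
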