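# Methods

This note records the models implemented in `coreplasma`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the estimator properties a user should know before trusting a
number.

## Flow models

All models describe steady, laminar, incompressible, fully developed,
axisymmetric flow in a cylindrical tube (radius R, length L) driven by a
pressure drop ΔP. Under these assumptions the shear stress is
τ(r) = ΔP·r/2L for *any* constitutive law; each model differs only in how
shear rate follows from stress.

* **Newtonian** and **power-law** profiles are the textbook closed forms.
  The power-law flow index n covers (0, 4]: blood cores in confined
  channels are reported both shear-thinning (n < 1, aggregating plasma
  suspensions) and mildly shear-thickening (n > 1, washed cells in buffer),
  so the bound leaves headroom on both sides.
* **Carreau** is a viscosity law, not a profile; the profile solver inverts
  μ(γ̇)·γ̇ = τ(r) per radius and integrates γ̇ from the wall inward.
  Because μ(γ̇)·γ̇ is strictly increasing and μ is bounded by the two
  plateaus, the root is bracketed by [τ/μ₀, τ/μ∞]; a vectorized bisection
  drives the bracket to 1e-12 relative width (convergence is
  unconditional). The integral uses the trapezoid rule on a dense uniform
  grid (default 4001 nodes) augmented with the requested radii, so
  evaluation points are exact quadrature nodes: in the constant-viscosity
  limit the integrand is linear and the solver reproduces the Poiseuille
  profile to machine precision, and halving the grid changes the centerline
  speed by < 1e-7 for shear-thinning parameters.
* **DPP** (double-parameter power fit) is a purely empirical shape,
  u = V_max(1 − k₁x²)(1 − x^{k₂}) with x = |r|/R; it carries no viscosity
  information and exists as the empirical benchmark that velocity-profile
  studies traditionally report.
* **Core–plasma** splits the tube at r = R − δ into a power-law core and a
  Newtonian plasma annulus. No slip at the wall, continuity of velocity
  and of shear stress at the interface, symmetry at the centerline. Both
  branches are closed-form. The printed-equation convention with a
  negative annulus term is replaced by the positive-magnitude profile, and
  shear rates are reported as magnitudes; this keeps all five models on
  one sign convention and matches how measured profiles are plotted.

The radial coordinate is signed with the centerline at zero and model
evaluation is even in r, so full-diameter profiles never need pre-folding.
Strict SI units are used everywhere inside the library; μm/mbar/mm/s/μL
min⁻¹/mPa·s conversions live exclusively in the I/O layer, because silent
unit slips are the dominant failure mode in formulas containing R⁴.

## Fitting

Models are fitted by bounded trust-region least squares on the velocity
residual, with termination at 1e-10 relative step/objective/gradient
tolerance and at most 5000 evaluations — deterministic, no random
restarts by default. Initial values: the viscosity-like parameters start
from the apparent viscosity (Poiseuille inversion of a measured flow rate)
when one is available, else from the conventional 3.5 mPa·s reference;
Carreau starts at its literature-typical time constant (3.31 s) and index
(0.36); DPP starts from the observed maximum speed.

Choices that were genuinely open:

* **δ in the core–plasma fit** is fixed to the optically measured CFL
  thickness by default and only floats on request. The optical boundary is
  the more reliable measurement, and fixing it keeps the core indices
  (K_cp, n_cp) interpretable; freeing δ turns the fit into a four-parameter
  problem with a much flatter objective.
* **μ_p** is a free parameter initialized at μ_app (with an option to pin
  it). The plasma annulus carries few points, so pinned fits are more
  stable but inherit any bias in the flow-rate measurement.
* **Weighting** is off by default (μPIV practice filters noisy vectors
  rather than weighting them); per-point 1/sd² weighting is opt-in. With a
  constant sd column the weighted fit equals the unweighted one up to
  optimizer rounding.
* The Carreau plateau ordering μ₀ ≥ μ∞ is enforced by fitting
  (μ∞, Δμ = μ₀ − μ∞ ≥ 0) internally, making the constraint a simple bound.

Two identifiability facts, measured on this implementation and worth
internalizing:

* **K_cp inherits amplified error.** The centerline speed scales as
  (ΔP/2K L)^{1/n}, so ln u carries the factor ln(ΔP/2KL)/n ≈ 20 linking K
  to n. At a representative bench condition (R = 25 μm, L = 10 mm,
  180 mbar, 60 points, 2% centerline-relative noise, δ fixed) the
  Cramér–Rao bound already puts the median relative error of K̂_cp at
  ~32% while n̂_cp sits near 4% and μ̂_p near 1.5%; the fitted estimator
  attains these bounds. Large spreads in reported consistency indices are
  an intrinsic property of velocity-profile fitting, not an optimization
  failure.
* **Carreau is weakly identified at high shear.** When λγ̇ ≫ 1 across
  essentially the whole tube, μ₀ and λ trade off along a near-flat valley;
  recovering them requires data spanning the plateau transition (low
  pressure) and tight termination tolerances. At typical microchannel
  shear rates only μ∞ and n_c are well determined — consistent with
  fitted λ being effectively constant across conditions.

Goodness of fit is the RMS velocity error, optionally split at |r| = R − δ
into core and CFL contributions (an empty region reports "absent", never
zero, and δ = 0 means everything is core). When a measured shear profile
is supplied, shear RMS errors are computed against each model's analytic
shear rate (the stress-balance inversion for Carreau). Model comparison
ranks by velocity RMS with ties broken by fewer free parameters, then
model name.

## Shear-rate profiles and hydrodynamic CFL

`numerical_shear_rate` folds a profile about the centerline (mirrored
radii averaged — this halves noise for symmetric full-diameter scans and
can be disabled for asymmetric flows), then differentiates with central
differences on the non-uniform grid, one-sided at the ends. An optional
local-polynomial smoother (window ≥ 3, default off) precedes
differentiation; finite differencing amplifies velocity noise by ~σ_u/h,
so noisy μPIV data generally needs either smoothing or dense averaging
before the changepoint fit is meaningful.

The changepoint fit minimizes the summed squared residual of the
continuous two-slope model (core line through the origin; CFL line
anchored to it at r_ip) over breakpoints constrained to 0 < r_ip ≤ R. A
penalty formulation that adds a length to a squared shear rate would be
dimensionally inconsistent, so the constraint is enforced as a hard bound.
The search scans every interior data radius with at least three points on
each side, solving the 2×2 normal equations per candidate in closed form,
then refines between the best candidate's neighbours by golden-section
search — deterministic, seed-free, and exact on the candidate grid. Fewer
than three points on a side, or indistinguishable slopes (a single
straight line), yield a degenerate estimate with δ_h = 0 rather than an
arbitrary breakpoint.

**Known bias.** The true two-phase shear profile *jumps* at the core
boundary (stress is continuous but viscosity is not), while the fitted
model is continuous at r_ip by construction. On ideal n_cp = 1 forward
data (δ = 5 μm, R = 25 μm, 0.25 μm grid) the global optimum — verified
against an independent brute-force dense scan — sits 2.1 μm inward of the
true boundary, independent of the viscosity contrast, so δ_h
systematically overestimates δ there; with a shear-thinning core
(n_cp = 0.9) core curvature partially offsets the jump and the bias drops
to 1.5 μm. The breakpoint is nevertheless *precise*: shear noise at 5% of
the maximum moves r_ip by at most two grid steps in ≳95% of trials. Treat
δ_h as a reproducible hydrodynamic landmark, not as an unbiased measure of
the optical CFL thickness; the package pairs the two (δ_o vs δ_h) without
assuming a sign for their difference. For strongly shear-thinning cores
under heavy noise the objective can become multimodal (curvature competes
with the interface kink), which is visible in the estimate jumping between
minima — inspect the shear profile before trusting a single number.

## Synthetic μPIV generator

`simulate_profile` evaluates a forward model on a uniform radial grid
(half or mirrored full-diameter layout, optionally excluding a near-wall
band where μPIV correlation fails), adds i.i.d. Gaussian noise, and clips
negative speeds to zero (speeds are magnitudes; clip counts are kept in
the profile metadata). Noise is homoscedastic by default, specified
either absolutely or as a fraction of the noiseless centerline speed; an
optional linear ramp σ(r) = σ(1 + c·|r|/R) emulates the near-wall
degradation of real correlation quality. Identical (spec, seed) pairs
regenerate bit-identical profiles.

`simulate_study_grid` emulates a typical in-vitro design: ten pressure
setpoints of 20–200 mbar at hematocrits of 5–20% in PBS and plasma, one
profile per cell, with per-cell seeds derived deterministically from the
base seed and the cell indices. The default ground-truth rule encodes the
qualitative trends such studies report: the CFL fraction of the radius
shrinks with hematocrit (0.28 − 0.8·Ht, clipped to [0.05, 0.45]); the
core is shear-thinning in plasma (n_cp = 0.9, protein-mediated
aggregation) and mildly shear-thickening in buffer (n_cp = 1.15); the
consistency index grows with cell content (K_cp = 3 mPa·sⁿ·(1 + 2Ht));
plasma is slightly more viscous than PBS (1.2 vs 1.0 mPa·s). The default
channel (R = 25 μm, L = 40 mm) puts the wall shear rate of the mid-grid
pressures inside the physiological microvascular band (~10²–4×10³ s⁻¹).

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: particle-image formation and
cross-correlation artifacts, depth-of-correlation averaging across the
focal plane, out-of-plane motion, spatially correlated noise, wall
position uncertainty beyond a simple exclusion band, and the blurred,
fluctuating core–CFL interface of a real suspension. Tests against this
generator validate the estimators' numerics and statistics under their own
assumptions, not μPIV physics.

## Problem sizes and numerical conventions

The test suite and the acceptance script use deliberately modest problem
sizes — 50-profile recovery experiments, 100 noise realizations for the
changepoint robustness check, 20-profile model comparisons, 60–120 point
profiles, 0.25 μm shear grids — chosen as the smallest designs whose
Monte-Carlo medians are stable to re-seeding. Degenerate inputs follow
fixed conventions: δ = 0 collapses the core–plasma model onto the power
law; an unidentifiable breakpoint reports δ_h = 0 with a degenerate flag
rather than a pseudo-estimate; quadrature and root-finding failures raise
a numerical error naming the offending radius instead of returning partial
results. Profiles overhanging the wall by less than 2% of R (μPIV wall
localization uncertainty) are clamped with a logged count; larger
overhangs are rejected.
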