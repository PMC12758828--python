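# coreplasma

Two-phase core–plasma modelling of microvascular blood flow.

In microchannels and microvessels below ~100 μm, blood stops behaving like a
homogeneous fluid: red blood cells migrate toward the centerline, leaving a
plasma-rich **cell-free layer (CFL)** along the wall. `coreplasma` is a
library and command-line tool for people who measure radial velocity
profiles in such channels (typically by micro-particle image velocimetry,
μPIV) and want to (a) fit rheological models to them, (b) estimate the
hydrodynamic CFL thickness, and (c) compare how well competing models
describe the flow.

## Models

Five velocity-profile models for pressure-driven flow in a cylindrical tube
of radius *R* and length *L* under pressure drop ΔP:

| Model | Velocity profile | Parameters |
|---|---|---|
| Newtonian | u(r) = ΔP(R² − r²)/(4μL) | μ |
| Power law | u(r) = (ΔP/2K_pL)^{1/n_p} · n_p/(n_p+1) · (R^{(n_p+1)/n_p} − r^{(n_p+1)/n_p}) | K_p, n_p |
| Carreau | μ(γ̇) = μ∞ + (μ₀−μ∞)[1+(λγ̇)²]^{(n_c−1)/2}; u(r) by solving μ(γ̇)γ̇ = ΔP·r/2L and integrating γ̇ inward from the wall | μ₀, μ∞, λ, n_c |
| DPP (empirical) | u(r) = V_max(1 − k₁(r/R)²)(1 − (r/R)^{k₂}) | V_max, k₁, k₂ |
| **Core–plasma** | power-law core for r < R−δ, Newtonian plasma annulus for r ≥ R−δ, velocity-continuous at the interface, no slip at the wall | μ_p, K_cp, n_cp, δ |

The core–plasma model is the centerpiece: it makes the CFL explicit, with a
Newtonian plasma annulus of thickness δ and viscosity μ_p wrapped around a
power-law RBC-rich core (consistency K_cp, flow index n_cp). Shear stress
τ(r) = ΔP·r/2L is continuous everywhere; the shear *rate* jumps at the
interface because the two phases have different viscosities.

Two companion computations:

* **Apparent viscosity** by Poiseuille inversion, μ_app = πR⁴ΔP / 8QL, from
  a measured flow rate Q.
* **Hydrodynamic CFL thickness** δ_h: the shear-rate magnitude profile
  γ̇(r) = |du/dr| is approximated by two straight lines — γ̇₁ = m₁r through
  the origin (core) and γ̇₂ = m₂(r − r_ip) + m₁r_ip (CFL), continuous at the
  breakpoint r_ip — and the breakpoint minimizing the summed squared
  residual under r_ip ≤ R gives δ_h = R − r_ip and the boundary shear rate
  γ̇_d = m₁r_ip.

All internal computation is strict SI; the CLI and file formats speak the
laboratory dialect (μm, mbar, mm/s, μL/min, mPa·s).

## Worked example

Generate a synthetic μPIV profile from a known two-phase ground truth
(R = 25 μm, L = 10 mm, 180 mbar, δ = 5 μm, 0.2% noise), fit all five
models, and estimate the CFL:

```sh
coreplasma simulate --model coreplasma \
  --params '{"mu_p": 1.2e-3, "K_cp": 3e-3, "n_cp": 1.0, "delta": 5e-6}' \
  --geometry-radius-um 25 --geometry-length-mm 10 --dp-mbar 180 \
  --n-points 120 --noise 0.002 --seed 7 --out demo.csv

coreplasma fit demo.csv --geometry-radius-um 25 --geometry-length-mm 10 \
  --dp-mbar 180 --delta-o-um 5 --out fit.json
# carreau: rms_velocity = 4.057 mm/s
# coreplasma: rms_velocity = 0.2452 mm/s
# dpp: rms_velocity = 1.649 mm/s
# newtonian: rms_velocity = 13.07 mm/s
# powerlaw: rms_velocity = 4.056 mm/s

coreplasma cfl demo.csv --geometry-radius-um 25 --geometry-length-mm 10 \
  --dp-mbar 180 --delta-o-um 5 --smooth-window 7 --out cfl.json
# delta_h = 7.252 um, gamma_d = 5340.4 1/s
```

The two-phase model fits its own kind of data an order of magnitude better
than the single-phase alternatives (0.245 mm/s RMS vs 4–13 mm/s), and the
fitted parameters land on the truth: `fit.json` reports
μ_p = 1.20 mPa·s, K_cp = 3.23 mPa·sⁿ, n_cp = 0.991 against the generating
(1.2, 3.0, 1.0). The hydrodynamic CFL estimate (7.25 μm) overshoots the
true 5 μm: the continuous two-slope model cannot represent the shear-rate
jump at the core boundary, so its breakpoint sits systematically inward —
a known property of the estimator discussed in `docs/methods.md`.

The same pipeline is available as a library:

```python
import coreplasma as cp

geom = cp.ChannelGeometry(radius=25e-6, length=10e-3)
truth = cp.CorePlasmaParams(mu_p=1.2e-3, K_cp=3e-3, n_cp=1.0, delta=5e-6)
spec = cp.SyntheticSpec(model_kind="coreplasma", params=truth,
                        geometry=geom, delta_p=18000.0, noise_sigma=0.002,
                        seed=7)
profile = cp.simulate_profile(spec)
table = cp.compare_models(profile, options=cp.FitOptions(delta=5e-6))
shear = cp.numerical_shear_rate(profile, smooth_window=7)
estimate = cp.fit_piecewise_shear(shear, geom.radius)
```

`simulate_study_grid` builds full factorial designs (hematocrit × pressure
× suspending medium) with per-cell deterministic seeds and known ground
truth for every profile.

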