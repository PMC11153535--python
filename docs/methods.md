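# Methods

This note documents the models behind `ivoct`, the choices that were
genuinely open, and what the shipped defaults do and do not capture.

## Problem

Intravascular OCT (IVOCT) images a vessel wall with near-infrared light from
a catheter-mounted lens while the opaque blood in the lumen is displaced by
injected normal saline. The package simulates the whole acquisition cycle in
an idealised straight lower-extremity artery: pulsatile blood inflow, saline
injection through the guiding catheter, the resulting erythrocyte
(haematocrit) field, Lambert–Beer image formation along each radial A-line,
automatic pull-back triggering, and quantitative scoring of the scan. Its
purpose is to compare injection schedules — conventional continuous
injection against a cyclic intermittent scheme — by image quality delivered
per millilitre of saline injected.

## Geometry and coordinates

Cylindrical axisymmetric coordinates `(r, z)`; `z = 0` at the guiding
catheter outlet, increasing downstream. Config lengths are millimetres; a
single conversion layer produces SI for the solver. Defaults (radii from the
axis): OCT catheter 0.45 mm, guiding catheter bore 0.9 mm / outer wall
1.0 mm, vessel lumen 2.0 mm, vessel outer wall 2.37 mm, extramural tissue
out to 5.0 mm. The 0.37 mm wall is split into intima/media/adventitia in
equal thirds by default (no finer split is established; configurable). The
stated total tissue extent (2.37 + 2.64 mm) overshoots the stated 5 mm total
radius by 0.01 mm; we trim the extramural layer to end at exactly 5.0 mm.
The flow domain spans `z ∈ [−20, 80]` mm — long enough to contain the 50 mm
scan span with entrance and outlet margins; the guiding catheter occupies
`z < 0`. Vessel-wall elasticity (FSI), curvature, branching and catheter
eccentricity are out of scope.

## Mixture laws

Blood is a two-phase mixture of erythrocytes (haematocrit `X_e`) in a
plasma/saline continuum:

* viscosity: Einstein suspension law `μ = μ_p (1 + 2.5 X_e)`, with plasma
  viscosity identified with saline viscosity;
* density: volume-weighted, `ρ = X_e ρ_e + (1 − X_e) ρ_s`, which with whole
  blood at 1056 kg/m³ (45% haematocrit) and saline at 1000 kg/m³ implies an
  erythrocyte density of 1124.4 kg/m³ and a whole-blood erythrocyte mass
  fraction of 0.479;
* diffusivity: Stokes–Einstein `D = kT / (3π d_e μ)` with `d_e` the
  equivalent-volume sphere diameter of a 90 µm³ red cell (5.56 µm).

Body temperature (310 K) and plasma viscosity (0.9 mPa·s) are calibrated
defaults: they are the physiologically standard pair that reproduces the
reference diffusivities 4.27×10⁻¹⁴ m²/s (whole blood) and 9.08×10⁻¹⁴ m²/s
(saline) to three significant figures. Both are configuration, not
constants. Non-Newtonian rheology is a non-goal.

## Waveforms and dosage

The cardiac cycle is 0.8 s; nine cycles (7.2 s) are simulated. Blood inflow
is a parametric femoral-like triphasic template (sharp systolic peak at 15%
of the cycle, brief early-diastolic reversal, weak late-diastolic forward
flow), replaceable by user-supplied samples. Its peak is calibrated so the
peak lumen Reynolds number in the 4 mm vessel is 770 (≈4.38 mL/s); the
template's cycle mean is ≈0.71 mL/s (≈43 mL/min), a realistic resting flow
for a 4 mm lower-extremity artery.

Saline schedules share one peak rate, 4.5 mL/s — within the 5–10 mL/s
clinical flushing ballpark and chosen jointly with the other defaults so
that (i) the continuous scheme over `t ∈ [0.8, 4.0]` s integrates to
14.4 mL, (ii) the intermittent scheme (power-law ramp with exponent
`a = 0.8` over the first 0.4 s of cycles 2–5, mirrored fall) delivers
`4.5·0.8/(a+1) = 2.0` mL per cycle, 8.0 mL total, and (iii) the combined
blood-plus-saline peak Reynolds number is ≈3.1×10³. Dosage
`V = ∫ Q(t) dt` uses trapezoidal quadrature on the waveform's native knots
(exact for the piecewise-linear continuous scheme; the power-law ramps are
sampled at 0.25 ms, keeping the quadrature error below 10⁻⁵ relative).
Injection begins with the second cardiac cycle, and the continuous scheme's
rectangle carries 0.02 s linear on/off ramps centred on the switch times so
its integral equals the ideal rectangle exactly.

## Flushing solver

Incompressible axisymmetric flow with a composition-dependent viscosity,
plus conservative transport of the erythrocyte phase. Because the
blood/saline density contrast is < 6% and transport is overwhelmingly
advective (Péclet ≈ 10¹⁰–10¹¹), the velocity field is treated as solenoidal
and the pressure projection uses a constant reference density; composition
feedback enters through viscosity (and density wherever mixture fields are
reported). Transporting the haematocrit `X_e` is exactly equivalent to
transporting erythrocyte mass, since `ρ w_e = ρ_e X_e` is linear in `X_e`.

Discretization: staggered (MAC) finite volumes, `nr × nz` uniform cells over
`r ∈ [0.45, 2.0]` mm, `z ∈ [−20, 80]` mm; the guiding catheter wall is a
blocked-cell region with no-slip faces. Species advection is second-order
upwind with a minmod limiter (flux form, conservative to round-off — the
mass-balance audit on production runs closes to ~10⁻¹² relative); momentum
advection is first-order upwind. Diffusion is implicit in `r` (batched
tridiagonal solves; unconditionally stable across the thin annular gap) and
explicit in `z`. Pressure projection solves one prefactorized sparse Poisson
system per sub-step; the discrete divergence after projection is at solver
round-off. The time step adapts to an advective CFL limit of 0.5 and lands
exactly on the 0.01 s snapshot cadence. Boundary conditions: plug inflow on
both inlet annuli (saline at mass fraction 0 between the catheters, blood at
0.479 outside the guiding catheter), `p = 0` with outflow species treatment
at `z = 80` mm, no-slip/no-flux walls. The vessel starts full of whole
blood. The solver contains no random numbers; runs are bit-reproducible.

Turbulence fidelities:

* `laminar` — molecular transport only (used for the annular-Poiseuille
  oracle tests).
* `laminar_eddy` (default) — algebraic mixing-length eddy viscosity,
  `ν_t = min(κ d_w, 0.09·gap)² |S|`, with a regime-level transition ramp:
  the closure scales in as the instantaneous inlet duct Reynolds number
  (built from the combined inlet flow rates, lumen diameter and saline
  properties) crosses 500–2000, so low-Re runs remain exactly laminar while
  the injection-phase jet and its recirculation see the closure. Eddy
  species diffusivity uses turbulent Schmidt number 0.7 — physically
  required for jet mixing even though the laminar species law carries only
  molecular diffusion. ν_t is capped at 10⁻⁴ m²/s.
* `rans_komega` — Wilcox (1988) k–ω with the standard production limiter
  (`P ≤ 10 β* k ω`) and a near-wall specific-dissipation floor
  (`ω ≥ 6ν/(β y²)` in wall-adjacent cells) as a reduced low-Reynolds
  treatment; same eddy diffusivity and cap.

Wall stress on the vessel inner wall: shear from a one-sided quadratic fit
through the two near-wall cells (exact for a parabolic profile), reported
positive when the fluid drags the wall in +z; normal stress is pressure plus
the viscous normal term, compression positive. During the reflux phase of
the second cycle (~1.0–1.2 s) the default desk-scale run produces a peak
shear of ≈17 Pa directed upstream, a few millimetres downstream of the
guiding catheter outlet — the jet/reflux-vortex signature, far above the
1.0–2.5 Pa physiological range. The magnitude is closure-limited: the
algebraic mixing-length model carries no turbulence transport and no
near-wall damping beyond `l = κ d`, so it sustains a sharper recirculation
(and roughly twice the peak wall shear) than a resolved low-Reynolds k–ω
solution of the same flow, and the peak grows rather than converges under
grid refinement. Wall stresses from this solver are order-of-magnitude
statements, not predictions.

## Optics

A collimated beam leaves the OCT catheter wall and propagates radially.
Lumen coefficients scale with haematocrit
(`φ_a = (X_e/0.45)·0.19`, `φ_s = ((1−X_e)/0.55)(X_e/0.45)·45.36` per mm,
anisotropy 0.9779, `φ_t = φ_a + φ_s(1−δ)`); solid tissues use tabulated
`φ_t`/`φ_b` per layer (intima 0.67/0.73, media 0.48/0.69, adventitia
0.53/0.68, extramural 0.5/0.5 per mm). Residual irradiance follows
`M(r) = exp(−∫φ_t dx)`; the detected signal is
`I(r) = β φ_b(r) E₀ exp(−2∫φ_t dx)` (round-trip exponent); grayscale is
`G = 255 I/I_max` with `I_max = αβE₀·φ_t(45%)`, clipped and rounded
half-to-even. `E₀` is normalised to 1 — only ratios matter. The wall
residual ratio `M_w` is the single-pass `M` at the vessel inner wall
(2.0 mm), so a whole-blood lumen gives `M_w = exp(−1.1925·1.55) ≈ 0.158`
and pure saline gives exactly 1. Note the round-trip signal exponent and a
strict energy balance cannot both hold; the model verifies conservation in
the single-pass sense (`∫φ_t e^{−τ} dr = 1 − M(end)`). Radial sampling is
5 µm with trapezoidal cumulative integration; samples on material
interfaces take the inner medium's coefficients so homogeneous-segment
attenuation is exact. Speckle, coherence gating, focus and multiple
scattering are out of scope — the model is irradiance-based.

## Scan scoring

Pull-back: 20 mm/s for 2.5 s toward −z (50 mm, 251 frames 0.2 mm apart),
lens starting at `z = 60` mm so the scan covers `z ∈ [10, 60]` mm.
Acquisition starts automatically at the first 0.01 s sample whose `M_w` at
the start position reaches the clear-image-frame (CIF) threshold 0.75, and
then runs to completion regardless of later dips (sub-threshold frames are
recorded, not skipped). Clear imaging length (CIL) is the CIF-frame count
times the frame spacing — non-contiguous clear stretches all count, and an
all-clear scan is capped at the 50 mm pull-back length. Overall quality is

    γ = f₁·mean(M_w) + f₂·(1 − σ/0.25),   f₁ = 0.7, f₂ = 0.3,

where σ is the *population variance* of the per-frame `M_w`; 0.25 is the
largest variance a [0, 1]-valued series can attain, so γ ∈ [0, 1] whenever
f₁ + f₂ = 1.

## Synthetic fields

`make_fixture` provides closed-form haematocrit fields — uniform lumen, an
advancing saline front, and cyclic erythrocyte slugs — that exercise the
optics → scoring → imaging chain deterministically in seconds. They
reproduce the geometry of the solver's fields, not their physics: passing
fixture-based tests validates the imaging and scoring pipeline, not the
hemodynamics.

## Problem sizes and defaults

The documented solver default is a 64×400 grid; the package's desk-scale
experiments (tests and the acceptance script) run the coupled
flushing-plus-scan pipeline on a reduced 32×200 grid with the
`laminar_eddy` closure, which resolves the annular gap with ≈48 µm cells
and completes a scheme in minutes on one core. On this grid the continuous
scheme triggers its pull-back at ≈1.2 s and scores γ ≈ 0.79; the
intermittent scheme scores γ ≈ 0.73 (a ≈7% drop) with a clear imaging
length well above the 24 mm clinical minimum, at 44.4% less saline. Frame-level
quantities (trigger time, CIL, γ) shift by a few percent between grids;
the schedule dosimetry and mixture/optics constants are grid-independent.

## Known limitations

* The reduced turbulence closures bracket, rather than reproduce, a
  resolved low-Re k–ω solution; quantitative fields (γ, CIL, wall stress)
  carry solver-fidelity spread and are asserted as bands, not equalities.
* Rigid straight vessel, coaxial catheters, plug inlets.
* The blood waveform is a literature-shaped template, not patient data.
* Irradiance-based optics: no speckle or interferometric effects, so
  rendered images are smoother than clinical OCT frames.
* Axial diffusion is explicit; extremely diffusive configurations (eddy
  viscosity far above the 10⁻⁴ m²/s cap) would demand smaller time steps.
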