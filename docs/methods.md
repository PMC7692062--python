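# Methods

This note documents the model, its parameters and their provenance, the
numerical scheme, the design choices that were genuinely open, and the
known limitations of both the simulator and the estimation pipeline.

## Physical model

The sample is a sphere of moist plant tissue (the packaged presets describe
whole pears) characterized by its water volume fraction φ(r,t), temperature
T(r,t) and radius R(t).  Both fields obey advection–diffusion equations in
spherical symmetry; the advection velocity is the pointwise shrinkage
velocity v_s = α₀·D_eff(T)·∂φ/∂r, proportional and opposite to the
diffusive volumetric water flux.  The boundary is material, dR/dt = v_s(R):
shrinkage is an output of the transport problem.  With α₀ = 1 (ideal
shrinkage, the default) the volume lost equals the volume of water removed,
which forces the identity 1 − V/V₀ = φ₀(1 − X/X₀) along every trajectory —
the test suite checks it to 0.5%.  α₀ = 0 recovers a rigid solid; values
between scale the volume response.

The surface couples to the chamber air through evaporative (Robin)
conditions: the water flux is driven by the vapor-concentration difference
between the surface — at temperature T_b, with relative humidity RH_b given
by the desorption isotherm at the surface moisture — and the bulk air; the
heat condition balances conduction against convective heat transfer minus
the latent heat carried by the evaporated water.  Negative fluxes
(condensation during cool-humid pauses) are permitted and do occur late in
intermittent programs.

Three variants share this water model:

* `full` — temperature PDE with conduction, shrinkage advection and the
  evaporative surface sink;
* `lumped` — a single energy balance for a spatially uniform temperature,
  valid because the thermal diffusivity (~1.4×10⁻⁷ m²/s) exceeds the water
  diffusivity (~2×10⁻¹⁰ m²/s) by three orders of magnitude.  After the
  brief internal thermal equilibration (~1–2 h for a 5 cm sphere,
  R²/D_T ≈ 1.4 h) it tracks the full model's boundary temperature to
  ~0.1 K; during that first transient the two legitimately differ by up to
  ~2 K because the full model resolves the radial temperature gradient;
* `isothermal` — T ≡ T∞(t); useful for the estimation pipeline's
  assumptions and for analytic-oracle comparisons, but known to be
  inadequate for predicting real dehydration curves of large cold-loaded
  samples, since D_eff at the 15 °C loading temperature is five times
  smaller than at 50 °C.

## Ambient programs

A program is a cyclic list of constant stages (duration, T∞, RH∞, U∞).  The
canonical cycle is 10 h convective drying (40 or 50 °C, RH 15%, U 1.28 or
2.66 m/s), a 7 h hot-humid pause (same temperature, RH 80%, U 0.1 m/s) and
a 7 h cool-humid pause (17 °C, RH 80%, U 0.1 m/s).  Stage switches use the
smooth step θ_δ(t) = (1 − tanh(t/δ))/2 with δ = 0.1 h, applied identically
to all three ambient variables; this represents the ~30 min a real chamber
needs to change state and keeps the forcing C∞ for the stiff integrator.

Switch-on transient: programs accept an optional `startup` ambient (default
15 °C, RH 0.80, U 0.1 m/s — lab/night conditions) from which the chamber
ramps at t = 0.  The ramp is centered 3δ after t = 0 so the run begins at
the startup values.  This matters physically: at 15 °C the convective
heating from a chamber already at stage-C conditions (several hundred W/m²)
would overwhelm evaporative cooling (tens of W/m²), so the observed slight
initial dip of the surface temperature below 15 °C can only arise while the
chamber itself is still cool and drying is driven by the humidity gap.
With the ramp the model reproduces a dip of a few tenths of a kelvin.

## Parameters and provenance

* Effective diffusivity: D_eff = D₀·exp((E/R_g)/T) with calibrated
  constants D₀ = 4.00012×10⁻⁵ m²/s, E/R_g = −3872.63 K.  The exponent
  convention (E/R_g)/T is the one consistent with the calibrated pair
  D_eff(40 °C) = 1.703×10⁻¹⁰ and D_eff(50 °C) = 2.497×10⁻¹⁰ m²/s (a
  negative activation temperature then gives the physical increase with T).
  Note the published constants reproduce the 50 °C value only to ~0.12%
  because all quantities are rounded to 4–6 digits; tests use tolerances
  that respect this rounding floor.  An exponential moisture-dependent law
  D(φ,T) is available; its exponent β defaults to 0 (the temperature-only
  law predicts the reference experiments well, so the extra parameter is
  unwarranted by default).
* Desorption isotherm: Henderson form RH = 1 − exp(−a·T·X^b), T in kelvin,
  X dry-basis.  The source fit for pears is not published numerically, so
  the defaults a = 0.033 K⁻¹(kg/kg)⁻ᵇ, b = 1.29 are **synthetic**: chosen
  once so that equilibrium moisture is ~0.25 kg/kg at RH 0.80/17 °C and
  ~0.04 kg/kg at RH 0.15/40 °C, typical fruit desorption magnitudes.  Both
  are config-overridable and should be refit for quantitative work on a
  specific cultivar.
* Product properties: two-component mixing (water + generic dry solid with
  ρ_s = 1500 kg/m³, C_ps = 1600 J/(kg·K), k_s = 0.21 W/(m·K)):
  volume-additive density, mass-fraction-weighted heat capacity,
  volume-weighted (parallel) conductivity; φ = 1 recovers pure water
  exactly.  These standard rules give a thermal diffusivity ≈ 1.4×10⁻⁷ m²/s
  at φ₀ ≈ 0.9.  (A value of ~9×10⁻⁸ m²/s has been quoted for pears; the
  difference is immaterial here since either value keeps D_T/D_eff ≫ 100,
  and no attempt is made to force agreement.)
* Water properties: Buck correlation for saturation pressure and the linear
  steam-table fit λ_v[kJ/kg] = 2501 − 2.361·(T − 273.15); both match steam
  tables to <1% over the operating range and are smooth, as the integrator
  requires.
* Transfer coefficients: Ranz–Marshall sphere correlations
  Sh = 2 + 0.6·Re^(1/2)·Sc^(1/3) (and Nu analogously), dry-air properties
  at the film temperature (Sutherland viscosity, power-law conductivity,
  D_va = 2.26×10⁻⁵·(T/273.15)^1.81 m²/s).  This choice reproduces the
  reported magnitudes: h_T ≈ 18–20 W/(m²·K) for a 5.3 cm sphere at
  1.28 m/s, the d^(−1/2) diameter dependence, and a ≈1.4–1.5 gain when the
  air speed doubles from 1.28 to 2.66 m/s.  The coefficient and exponents
  are exposed for sensitivity studies; humid-air corrections are neglected
  (<2% at these temperatures).
* Geometry/initial state: initial moisture X₀ and diameter d₀ per
  experiment (packaged presets); initial temperature 15 °C; initial water
  volume fraction from φ = (X/ρ_w)/(X/ρ_w + 1/ρ_s), e.g. X₀ = 5.64 →
  φ₀ ≈ 0.894.

## Numerics

Front-fixing (Landau) transform σ = r/R(t) maps the shrinking domain onto
the unit interval; the moving-mesh advection term this introduces is merged
into a fully conservative flux form.  The integrated state variables are
u_i = (R/R₀)³·φ_i and h_i = (R/R₀)³·ρ_pC_pp·T_i/(ρ_wC_pw) on cell-centered
finite volumes (default 200 cells, widths geometrically refined toward the
surface with a 0.05 boundary/center ratio), plus R/R₀ and the cumulative
evaporated volume.  In these variables the total water content is a
*linear* invariant of the semi-discrete system, which linear multistep
integrators preserve to roundoff — the water balance therefore closes by
construction (verified to 10⁻³ of the cumulative loss, typically ~10⁻⁶),
and the spherical center needs no special treatment because the r = 0 cell
exchanges no flux through its inner face.

The Robin conditions are enforced pointwise at σ = 1: at every
right-hand-side evaluation a warm-started 2×2 Newton iteration (scalar for
the isothermal/lumped variants, with a nested-bisection fallback) solves
for the surface pair (φ_b, T_b) such that the one-sided second-order
boundary gradients match the evaporative fluxes; the same discrete gradient
feeds the front velocity dR/dt, keeping boundary condition and front motion
discretely consistent.  Surface moisture is floored smoothly at 10⁻⁶ inside
property evaluations to avoid the isotherm's zero-moisture singularity.

Time integration is BDF (`scipy.integrate.solve_ivp`) with rtol 10⁻⁴ /
atol 10⁻⁷ on the scaled O(1) state, an analytically specified Jacobian
sparsity (tridiagonal field coupling plus dense columns for the
boundary-closure inputs and the radius), outputs every 0.25 h refined to
0.05 h within ±0.5 h of every stage switch, and a terminal event if the
radius falls below 10⁻² R₀.  A 130 h intermittent program at default
resolution integrates in a few seconds on one CPU; doubling the grid
changes the final moisture ratio by <10⁻³.

Degenerate inputs: an ambient in vapor-pressure equilibrium with the
initial state is an exact fixed point (drift <10⁻⁶ over 10 h); α₀ = 0
keeps R constant to roundoff; a constant dehydration series is rejected by
the curve fitter with a diagnostic error.

## Estimation pipeline

X(t)/X₀ is fit with a₀ + a₁e^(−b₁t) + a₂e^(−b₂t) + (1−a₀−a₁−a₂)e^(−b₃t),
which passes through 1 at t = 0 by construction and decays to a₀.  Sums of
exponentials are ill-conditioned, so the fit multi-starts (default 20
starts) from log-spaced rate triplets over [10⁻³, 1] h⁻¹ with a seeded
generator, under bounds 0 ≤ a₀ < 1, b_i > 0; non-convergence raises an
error carrying the best candidate.  The rate curve J = −dX_r/dt follows
analytically from the fit; the through-origin least-squares slope of J vs
X_r over the window X_r < 0.2 (config-exposed) is inverted as
D_eff = slope·R₀²·(V∞/V₀)^(2/3)/π², and ln D_eff is regressed on 1/T for
the Arrhenius constants.  The slope fit has no intercept because the
asymptotic law passes through the origin.

On simulated rigid-sphere isothermal curves run to near-equilibrium (~6
diffusion times; the reference experiments likewise ran to X/X₀ ≈ a₀) the
pipeline recovers the input diffusivity to ~2.5% and, across two
temperatures, the activation temperature E/R_g to well under 5% — the
small windowing bias is common to both temperatures and cancels in the
regression.

Known bias: applied to a *strongly shrinking* sample (φ₀ ≈ 0.9), the
asymptotic law underestimates D_eff by ~25–30%, because within the
X_r < 0.2 window the volume (≈0.29 V₀ at the window edge) is still far
from its asymptote (≈0.11 V₀), so the (V∞/V₀)^(−2/3) geometric correction
overshoots the actual shrunken radius.  This is a property of the published
procedure itself, not of its implementation; estimates made with it are
self-consistent as long as the forward model is calibrated with values
derived the same way.

## Synthetic data

`generate_synthetic_curve` produces dehydration curves either from a
multi-exponential law or by resampling a simulated trajectory, with
additive i.i.d. Gaussian noise (default sd 0.005 on the X/X₀ scale,
matching the scatter of typical gravimetric measurements) and a seeded
generator for bitwise reproducibility.  It emulates measurement noise only:
real curves additionally carry correlated errors (balance drift, sample
handling between weighings) and sample-to-sample biological variability,
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not field accuracy for any particular fruit batch.

## Testing strategy

The published validation against experimental dehydration curves
(R² > 0.99) cannot be reproduced on the desk because those data exist only
as figures.  The suite therefore validates the simulator against
independent structure: the classical diffusion-series solution for a rigid
isothermal sphere (<0.5% relative down to X/X₀ = 0.03), exact discrete
water balance, the ideal-shrinkage identity, lumped/full agreement,
simulator-in-the-loop recovery of a known Arrhenius law, and the reported
phenomenology of intermittent drying: the transient surface-temperature dip
at switch-on, the tens of hours the sample needs to approach the chamber
temperature, slight rehydration in late cool-humid pauses, and the
persistence of internal moisture gradients through pause stages for ~5 cm
samples.

## Limitations

Spherical symmetry only; no case-hardening, cracking or stress mechanics;
a single lumped diffusivity rather than multi-mechanism moisture transport;
dry-air transfer correlations; desorption/adsorption hysteresis is ignored
(the desorption branch is used during rehydration episodes too); the
default isotherm constants are synthetic placeholders for cultivar-specific
fits; and the model intentionally predicts near-uniform internal
temperature, whereas measurable center/surface differences have been
reported experimentally for pears — reproducing that gap is out of scope.
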