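# Methods

This note documents the models, numerical choices and calibration behind
`corneaionto`, and what the synthetic-data tests do and do not demonstrate.

## Electrical model

The cornea is treated as four planar resistive layers in series (tear film
12 µm / epithelium 50 µm / stroma 430 µm / endothelium 20 µm; total
512 µm) with electrical conductivities 1.5 / 4·10⁻⁴ / 0.25 / 6.6·10⁻³ S/m.
All layers carry the same current density J = I/A; per-layer resistance is
L/(σA) and the stack is strongly epithelium-dominated (>96 % of the
~1.15 kΩ total). No shunt or limbal pathway is modelled.

**Cross-sectional area.** The exposed corneal disc is taken as a circle of
radius 0.6 cm (A = 1.13097 cm²), the unique area consistent with the
protocol's stated current-density pairs (0.5 mA ↔ 0.442 mA/cm², …,
500 mA ↔ 442.1 mA/cm²); the back-derived area is consistent across all
nine pairs to <0.1 %. A is configurable.

**Joule source and the compliance limit.** The volumetric heat source in
each layer is `Q = source_scale · J_eff²/σ`. `source_scale` is a
dimensionless calibration factor (raw ohmic dissipation at 1). `J_eff`
uses the *delivered* current `I_eff = min(I, V_c / R_total)`: a real
constant-current supply saturates at its compliance voltage, and the
512 µm stack at ~1.15 kΩ cannot draw 500 mA from any ophthalmic device
(it would take ~574 V). The calibrated configuration uses
V_c = 20.65 V — within the 15–40 V compliance range typical of clinical
iontophoresis units — so the 500 mA setpoint delivers ≈18 mA of heating
current while all clinical setpoints (≤ 7 mA) pass through unchanged.
Setting `compliance_voltage_V: null` recovers the unlimited quadratic
source.

## Thermal model

Transient 1-D Pennes bioheat equation on the depth axis x ∈ [0, 512] µm:

    ρc ∂T/∂t = ∂/∂x(k ∂T/∂x) + ω_b ρc (T_body − T) + Q_met + Q_joule

- geometry: planar 1-D (corneal curvature ≫ thickness); x = 0 at the
  anterior tear surface;
- anterior boundary: −k ∂T/∂x = h_conv (T − T_ambient) + e_evap
  (convective plus constant evaporative flux);
- posterior boundary: −k ∂T/∂x = h_post (T − T_body);
- perfusion ω_b and metabolic heat are per-layer parameters, zero by
  default (ex vivo tissue);
- initial condition: uniform baseline temperature.

**Discretisation.** Conservative finite volumes on a uniform grid whose
nodes coincide with every material interface (dx must divide the layer
positions; 2 µm default → 257 nodes, so every layer holds ≥3 nodes).
Interface conductances use the harmonic mean of adjacent nodal k, which
conserves flux across discontinuities. Time stepping is the θ-method with
θ = 1 (backward Euler) by default and θ = 0.5 (Crank–Nicolson) available;
at dt = 0.1 s and µm-scale dx the explicit diffusion number is ≫ ½, so an
implicit scheme is mandatory. Backward Euler is also L-stable, which
matters for the near-Dirichlet boundary tests (Crank–Nicolson rings at
stiff Robin boundaries). The tridiagonal systems are solved directly each
step; a 600-step protocol solve takes ~10 ms. A run-to-steady-state mode
stops when the per-step change falls below 10⁻⁶ °C.

Verified numerical properties (all in the test suite): exact preservation
of a boundary-equilibrated uniform state; per-step enthalpy balance on an
insulated slab to 10⁻⁶ relative; agreement with the analytic Fourier-series
solution of the clamped slab to 0.1 %; grid-convergence of reported surface
temperatures below 0.05 °C under dx, dt halving; monotone surface
temperature in current and time across the nine-current protocol.

## The calibrated parameter set

The exact thermal constants and boundary coefficients behind the reference
temperature simulations are not available, so the shipped
`reference_calibrated.yaml` is a *calibration*: a single parameter set, fitted
once by least squares and pinned, that jointly reproduces the reference
temperature summary (surface 82.1 °C at 500 mA/10 s; epithelium 146 °C,
tear film >100 °C, posterior stroma 48.2 °C, endothelium 42.7 °C at
500 mA/60 s; surface rise ≈48 °C at 10 s; posterior rise ≤0.2 °C at
≤2 mA) and the qualitative 10 s safety partition (≤2 mA thermoneutral,
3 mA physiological, 500 mA damage). No quantity is tuned per target.

Fitted values: source_scale = 0.694, h_conv = 12.8 W/m²/K (e_evap = 0),
h_post = 1.14 W/m²/K, k_epithelium = 0.098, k_stroma = 8.2·10⁻⁴,
k_endothelium = 0.057 W/m/K, with ρ = 1050 kg/m³, c = 3800 J/kg/K
(tear film: water values) and V_c = 20.65 V. Baseline, ambient and
posterior temperatures are all 35.0 °C (mid/upper ocular baseline band),
modelling a thermostatted, humidity-saturated diffusion chamber; the
zero-current state is then an exact equilibrium.

**What these values mean.** The fitted layer conductivities are far below
those of hydrated tissue (~0.58 W/m/K). They should be read as *effective*
transport coefficients of the reference model, not tissue properties: with
water-like diffusivity the 512 µm stack equilibrates thermally in ~2 s,
which is incompatible with a reference profile that still grows from 82 to
146 °C between 10 and 60 s while holding a ~100 °C anterior–posterior
contrast. Reproducing that shape requires strongly hindered depth
transport, and the calibration localises it in the layer conductivities.
For physically-motivated exploration use `cornea_default.yaml`
(literature properties, raw source) and treat its outputs as a different
model, not a cross-check of the calibrated one.

Two printed intermediate-current values are *not* reproducible under any
single linear-PDE configuration with a quadratic (or clipped-quadratic)
source, because they scale sub-quadratically between adjacent currents:
a 3 mA surface of 37.3–37.6 °C alongside a 2 mA surface ≤36 °C would need
ΔT(3)/ΔT(2) ≈ 3.6 > (3/2)², and low-current rises of 0.5–0.7 °C are
likewise inconsistent with the 48 °C rise at the clipped extreme current.
The calibrated set reproduces the qualitative zone partition instead
(3 mA lands at ≈36.3 °C, physiological); the discrepancy is documented
here rather than absorbed by per-current re-tuning.

## Thermal safety classification

Four ordered zones: thermoneutral (≤36 °C, within/below the ocular
baseline band), physiological (36–41 °C), caution (41–43 °C), damage
(≥43 °C). Thresholds are right-closed upward — exactly 43 °C classifies as
damage — and configurable. "Surface temperature" is the anterior-region
(tear film + epithelium) maximum; the tear-node and epithelium-surface
conventions are selectable. The safe window reports, per time point, the
largest current whose surface classification stays at or below each zone.
Cumulative thermal-dose models (CEM43, Arrhenius kinetics) are out of
scope; classification is by fixed thresholds only.

## Fluorescence quantification

Emission scans are on the instrument grid 290–450 nm at 10 nm steps.
Because 345 nm falls between grid nodes, peak lookup uses the nearest node
with ties broken toward the longer wavelength (returning the 350 nm node);
an optional local-parabola mode interpolates the apex instead. Calibration
is ordinary least squares of peak intensity on concentration with a free
intercept (the line is not forced through zero), requiring ≥3 distinct
standards; prediction inverts the line on the (triplicate-averaged)
intensity and flags results outside the 0.125–2 mg/ml linear range as
extrapolated — notably the 2.7 mg/ml extreme-current readout, which
exceeds the validated range and is reported as a flagged extrapolation,
not a measurement. Background subtraction is available as an optional
pre-step (off by default). Inner-filter correction and deconvolution of
endogenous tissue fluorescence are out of scope.

## FTIR pipeline

Stages are typed and order-enforced (out-of-order calls raise):
raw → baseline-corrected → smoothed → group-averaged → second-derivative.

- **Baseline**: piecewise-linear through the mean points of configurable
  band-free anchor windows (linear extrapolation beyond the outer
  anchors), or a single polynomial; a global offset or tilt is removed
  exactly.
- **Smoothing**: 9-point Savitzky–Golay, polynomial order 2 (the common
  spectroscopy choice; order configurable), edges handled by the
  truncated-window polynomial fit. Exact on quadratics.
- **Averaging**: strict pointwise mean on identical grids (n recorded);
  grid mismatches raise rather than silently interpolating.
- **Second derivative**: Savitzky–Golay derivative kernel with respect to
  wavenumber; absorbance maxima appear as negative peaks.
- **Band integration**: trapezoidal integral of the rectified second
  derivative |d²A/dν²| over configurable windows (`bands.yaml`; limits
  are data, not code). Before rectification, points below a noise floor
  (3 × the robust 1.4826·MAD estimate of the derivative noise, by
  default) are zeroed: rectifying zero-mean noise otherwise adds a
  systematic positive background across the 3600 cm⁻¹ axis that corrupts
  whole-spectrum denominators. Signed-absorbance integration is retained
  as a mode.
- **Area percentages**: relative to the full-spectrum rectified area by
  default (so "total OH 38 %" is a share of all spectral area); a
  bands-only reference set is selectable. The OH envelope window
  (3000–3700 cm⁻¹) is a roll-up of the strOH/syOH/asyOH components and is
  excluded from the bands reference to avoid double counting.
- **Amide I**: dominant component = most negative second-derivative point
  in 1600–1700 cm⁻¹; assignment ≥1660 β-turn, 1650–1659 α-helix, <1650
  β-sheet/random coil, with the 1660 edge assigned upward.
- The water combination band check returns ν_bend + ν_stretch exactly as
  conventionally stated (1640 + 3400 = 5040 cm⁻¹); this does not match
  the observed 2129 cm⁻¹ association band and the discrepancy is
  surfaced, not silently corrected.

Known bias: two Savitzky–Golay passes attenuate absolute |d²| band areas
by ~5–8 % for the default band widths. Area *percentages* are ratios and
cancel the attenuation (verified to ±2 % absolute in the recovery tests);
absolute areas should be compared only between spectra processed with the
same kernel.

## Group statistics

Classical one-way fixed-effects ANOVA (between/within decomposition).
Degenerate inputs are defined explicitly: all-identical data give F = 0,
p = 1; zero within-variance with unequal means gives F = ∞, p = 0. Tukey
HSD uses the pooled MSW, the Tukey–Kramer standard error for unbalanced
groups, and adjusted p-values from the studentized-range distribution
evaluated numerically — no critical-value tables. Null calibration is
verified by simulation (type-I error in [0.04, 0.06] at α = 0.05; Tukey
familywise error ≈ α against the exact critical value). Eyes are treated
as independent samples (n = 10 per group), matching the source design;
no within-animal clustering is modelled.

## Synthetic data: what it emulates, and what passing tests show

Generators are pure functions of (parameters, seed) — fixed seeds give
bit-identical output.

- **Emission spectra**: Gaussian centred at 345 nm (FWHM 60 nm) with peak
  intensity linear in concentration (slope 1000 a.u. per mg/ml, intercept
  0) and 2 % relative Gaussian noise.
- **Calibration series**: the serial dilution {2, 1, 0.5, 0.25,
  0.125} mg/ml, intensity = 1000·c + 20 with 2 % relative noise.
- **FTIR spectra**: sums of Gaussian bands on the 400–4000 cm⁻¹, 2 cm⁻¹
  grid plus a smooth curved drift and 0.002 a.u. noise. Per-group presets
  (`ftir_presets.yaml`) encode the group-characteristic structure: amide-I
  1666 (control, 0.5–2 mA) / 1674 (3–5 mA, 500 mA) / 1659 cm⁻¹ (6–7 mA);
  strained-carbonyl (1821/1929 cm⁻¹) and thiol (2450–2530 cm⁻¹) bands only
  in the low-current preset; hydroxyl fractions declining from the control
  values strOH/asyOH/syOH = 31.1/4.7/2.2 %. Because the report quantity is
  a rectified-second-derivative area share, preset fractions are imposed on
  the analytic |d²| area (∝ amplitude/width), i.e. amplitudes are chosen as
  A ∝ fraction × σ. Band FWHMs (20–60 cm⁻¹ by band class) are recorded in
  the preset file.
- **Concentrations**: per-group truncated normals, n = 10, SD 0.1 mg/ml,
  means 0.5 mg/ml for ≤5 mA, 1.7 mg/ml at 6–7 mA, 2.7 mg/ml at 500 mA.

Passing recovery tests show that the *pipeline* is unbiased and correctly
calibrated on data with known ground truth and well-behaved (Gaussian
band, Gaussian noise) structure. They do not validate instrument-specific
effects absent from the generators: detector nonlinearity, atmospheric
compensation residues, Mie/scattering baselines, ATR distortion, or
endogenous-protein fluorescence. The ex vivo albumin concentrations
themselves are measurements, not model outputs; they enter the package
only as generator anchors and as the linear-range extrapolation flag.

## Problem sizes used by the shipped checks

The acceptance recomputation runs four transient solves (500, 2, 1,
0.5 mA) of 600 implicit steps on 257 nodes each. The statistical null
calibrations use 2000 seeded replicates of a 10-group × 10-sample design;
fluorescence calibration checks use 200–500 seeded replicate fits; the
FTIR recovery checks process 20 seeded sets of 10 replicate spectra
through the full chain. The whole suite completes in well under a minute
on one CPU.
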