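# Methods

This note records the model as implemented: governing equations,
parameter defaults with units, the numerical choices, what the synthetic
data emulate, and the limits of what the simulations show.

## Pipeline

The stages run serially with no feedback — histotripsy treatment is
assumed to finish before infusion begins:

    synthetic section → focal pressure map → Monte Carlo ablation
    → steady rt-PA field → fibrinolysis totals → cohort statistics

Every stage draws its randomness from streams spawned from one master
seed, so a full sweep is bit-reproducible from (config, seed).

## Synthetic thrombus sections

A section is a 2D grid of labels {background, RBC, fibrin} with physical
pixel size (default 7.4 µm, a red-blood-cell diameter). The thrombus
outline is an axis-aligned ellipse with axes 0.74/0.66 of the grid extent
(default 10 mm), leaving a background margin. Component territories are
produced by thresholding a Gaussian random field, smoothed isotropically,
at the quantile that realises the target fibrin fraction exactly (to
pixel quantisation); thresholded smooth fields give contiguous patches
with one correlation length, which is the texture visible in segmented
H&E sections of venous thrombus.

The patch scale is composition-dependent: the smoothing length is
`clustering_scale_mm × 2·min(f, 1−f)` for fibrin fraction f, with
`clustering_scale_mm = 0.5` by default. At balanced composition this
gives the ~0.5-mm component territories that make mixed ("half-half")
sections ablate in disjointed patches with viable RBC clusters trapped in
stiff fibrin surroundings; as one component dominates, the minority
component disperses into small pockets rather than pooling into lakes —
as residual red cells do in organised, fibrin-rich clot. Both regimes
matter: large territories in a strongly fibrin-dominated section would
create soft, RBC-rich neighbourhoods that ablate like acute clot, which
is not what dominated sections do.

Subgroup classification uses strict thresholds: fibrin fraction > 0.75 →
fibrin-dominant, < 0.25 → RBC-dominant, otherwise half-half (exactly 0.75
or 0.25 is half-half).

What the generator does **not** emulate: multi-scale texture, collagen
and other components of chronic thrombus, anisotropic fibrin alignment,
and the wide section-to-section geometry variation of surgical specimens.
Passing tests on these sections show the model machinery behaves
correctly and reproduces the subgroup phenomenology; they do not
reproduce any patient cohort's numbers.

## Focal pressure field

The therapy source is a 1.5-MHz focused transducer whose focal zone has
−6 dB widths of 4.3 mm (axial) × 0.7 mm (lateral). Only the widths are
published, so the in-plane peak-negative-pressure map is a separable
elliptical Gaussian matched to them, peaked at the thrombus centroid
(snapped to the nearest pixel centre so the peak is attained on-grid).
A measured map can be imported from delimited text and used anywhere a
`PressureField` is accepted. The Gaussian has no side lobes and decays
faster than a measured focal field beyond −6 dB, so ablation zones are
somewhat narrower than a hydrophone-driven calculation would give.

## Bubble growth model

For short (single-cycle) intrinsic-threshold pulses, the maximum bubble
radius in a Kelvin–Voigt medium is the closed form given in the README,
with defaults P₀ = 0.1 MPa, ρ = 1000 kg/m³, R₀ = 2.5 nm (intrinsic
nucleus), τ = 1/(2f) = 0.333 µs (the rarefactional half-period at
1.5 MHz, configurable). The dimensionless drive ξ_HA is implemented as
(p⁻ − P₀)/P₀ and is swappable; the elastic modulus enters twice — as a
tension deficit 6G/P₀ and in the Blake-brake confining pressure p_EFF.
When ξ ≤ 0 the nucleus does not grow (R_MAX = R₀): this is what makes
fibrin (G = 14 MPa) effectively untreatable while RBC regions (G = 4 kPa)
grow ~100–200 µm bubbles at 28–40 MPa.

The closed form was checked against full numerical Kelvin–Voigt
Rayleigh–Plesset integrations (half-cycle tension drive, blood-like
viscosity and surface tension): agreement is within ~35% over 28–40 MPa
and G up to 600 kPa, with both in the 10²-µm range. That is adequate for
a footprint model; the equation typography in the source literature is
ambiguous, and this parse was fixed by dimensional consistency plus the
numerical check.

Heterogeneity enters through G: at a nucleation site G is the arithmetic
mean of per-pixel moduli (fibrin 14 MPa, RBC 4 kPa, liquefied 0,
background excluded) within a 500-µm radius. On homogeneous sections the
outcome is insensitive to that radius over 100–1000 µm (tested); on
synthetic heterogeneous textures whose patch scale is comparable to the
radius it is **not** — the averaging radius then acts as a second texture
filter, a sensitivity worth remembering when interpreting heterogeneous
runs.

## Monte Carlo treatment

Each pulse: every thrombus pixel (including already-liquefied ones —
liquid still cavitates) draws u ~ U(0,1) and nucleates where
Φ((p⁻ − 26.8)/1.2) > u. The 26.8 ± 1.2 MPa normal-CDF sigmoid is the
intrinsic-threshold fit for clot; the SD is a parameter. Each nucleation
grows to R_MAX for the local G and ablates every still-intact RBC pixel
whose centre lies within R_MAX (closed-disk footprint); bubbles smaller
than half a pixel ablate nothing. Bubbles within a pulse are independent
(no shielding), and each pulse is an independent cloud — valid for slow
(<5 Hz) pulsing; at clinical 40-Hz rates this overestimates ablation.

Implementation notes: draws are made only where the probability exceeds
10⁻¹² (part of the random-stream contract, verified against a per-pixel
brute-force reference); the 500-µm modulus average is maintained as disk
sums updated incrementally as pixels liquefy, so it is exact after every
pulse; nucleations that cannot reach any intact RBC pixel are skipped via
a conservative coarse-grid occupancy check that does not change results.
Resolution: outcomes on well-resolved lesions (bubble radius ≳ pixel) are
stable within ~10% from 7.4 to 100 µm pixels; sub-pixel bubbles
(R < pixel/2) ablate nothing, so coarse grids suppress the marginal
ablation that fine grids show in stiff, dispersed-fibrin regions.

Bookkeeping: ablation area per pulse per repeat; hemoglobin at 0.03 ng
per ablated pixel at 7.4 µm, scaled by pixel area; catheter-insertion
hemolysis as 0.03 ng × RBC pixels within 0.84 mm of the thrombus centroid
(the Cragg–McNamara catheter cross-section). The histotripsy/catheter
hemoglobin ratio exceeds 1 robustly only for nearly pure RBC sections:
a few percent of dispersed fibrin stiffens every 500-µm neighbourhood
enough to shrink bubbles well below the pure-RBC size.

## rt-PA transport

Polar annulus centred on the catheter (r from 0.84 mm to the farthest
thrombus pixel), with the PDE of the README. Coefficients:

| symbol | meaning | default |
|---|---|---|
| Q | infusion rate | 0.0035 mL/s (12.5 mL/h) |
| n | porosity | 0.15 |
| U | fluid speed at catheter surface | 0.87 cm/s |
| a_I, a_II | longitudinal/transverse dispersion | 9.4, 3.4 ×10⁻⁶ cm²/s |
| D_clot | intact diffusivity | 2.5×10⁻⁶ cm²/s |
| D_ablate | liquefied diffusivity | 25×10⁻⁶ cm²/s |
| d | particulate diameter | 10⁻⁴ cm (Pe = Ud/nD_clot = 232) |
| k₂ | rt-PA/PAI-1 rate | 29 µM⁻¹s⁻¹ |
| C_p | PAI-1 concentration | 0.7 µM (calibrated, see below) |
| C_source | catheter rt-PA | 700 nMol |

Intact (porous) nodes carry D_r = a_I, D_θ = a_II and the flux-conserving
interstitial velocity v(r) = U·r_c/r, which reproduces U at the catheter
surface and is equivalent to Q/(2πBnr) with the effective catheter-to-edge
distance B = Q/(2πnUr_c) ≈ 0.05 cm. Liquefied nodes are fluid: isotropic
D_ablate and plug advection at speed U. The plug reading matters: under
the ~20 s⁻¹ PAI-1 quench the diffusion length √(D/k) is ~10 µm for either
diffusivity, so a diffusivity change alone would leave delivery
essentially unchanged; it is the sustained advection through the
liquefied channel that carries drug deeper, which is the enhancement the
model exists to capture. Quenching k₂C_p applies on all thrombus nodes
(PAI-1 is not depleted). Nodes outside the thrombus are absorbing (C = 0,
flowing blood clears drug), as is the outer boundary; the catheter
boundary holds C = C_source; θ is periodic.

C_p has no established in-situ value; 0.7 µM is of the order of
platelet-released PAI-1 inside clot and is documented as calibrated so
the quenched steady field penetrates ~1–2 mm (the narrow infusion channel
observed clinically). It is an exposed configuration value, and the
penetration-depth check is a consistency test of this configuration, not
an independent prediction.

Numerics: forward Euler, central differences for diffusion, first-order
upwind for advection; dt = 0.9 × the CFL bound (the advective limit dr/v
dominates at default parameters; at the reference resolution dr = 1 µm it
is ~0.11 ms). The solver refuses larger steps and verifies sign
preservation. The default desk-scale grid is dr = 0.02 mm, dθ = π/25
(penetration depth changes <5% on halving dr); the fine reference grid is
available through `PolarGrid`. Steady state is declared when
max|ΔC|/(C_source·Δt) < 10⁻³ s⁻¹ (first-crossing time reported; ~0.5 s at
defaults, well inside the ~10 s transient budget). A discrete flux audit
(inflow through the catheter face, outflow, quench losses, from the
telescoped discrete operators) balances total mass exactly for
homogeneous media and is asserted to 1% in tests. Dispersion coefficients
are the tabulated values by default; a power-law "correlation" mode
(exponents 1.2/0.2 longitudinal, 1.1/1.1 transverse in particulate
diameter and Péclet number, anchored to the tabulated values at
d = 10⁻⁴ cm) exists for sensitivity studies — the steady field changes by
<5% for d over 10⁻⁵–10⁻⁴ cm.

## Fibrinolysis

Fibrin pixels hold C_FIB = 950 nMol (RBC pixels 0); plasminogen 0.13 µM,
α₂-antiplasmin 0.44 µM, k₁ = 0.011, k₄ = 0.77, k₃ = 10 µM⁻¹s⁻¹. With
plasmin at its fast quasi-steady balance the FDP concentration is the
saturating exponential of the README; the closed form matches a direct
ODE integration of the two-step kinetics to <0.5% (the plasmin
equilibration time, ~0.2 s, is negligible against the 20-min exposure).
The rt-PA field is held at steady state for the whole exposure: the
transport transient (~1 s) is three orders faster than fibrinolysis.
Fibrin inside ablated zones keeps its full C_FIB — histotripsy lyses
cells, not fibrin. Per-pixel concentrations are sampled from the nearest
polar node; pixels under the catheter cross-section are excluded. Totals
are reported in nMol·pixel units (pixel area is constant within a
section, so the unit cancels in relative-FDP ratios).

## Statistics

One-way ANOVA with Tukey-HSD pairwise decisions (statsmodels), Pearson
correlation (scipy), and the z-score linear-regression coefficient: both
readouts z-scored across the 28–40 MPa sweep and fit by least squares;
the slope equals the Pearson correlation of the raw pairs. Sections with
zero hemoglobin variance (no ablation, e.g. nearly pure fibrin) yield an
undefined coefficient, reported as missing rather than coerced to zero.
Sweeps pool per-section means over the Monte Carlo repeats.

## Problem sizes

Defaults mirror the reference protocol (7.4-µm pixels, 1000 pulses, 10
repeats, 28–40 MPa plus 0-MPa baseline; fine transport grid available).
The test-suite and acceptance runs use desk-scale versions chosen as this
package's standard demonstration sizes: 25–50-µm pixels on 5–10-mm
sections, 100–1000 pulses, 1–10 repeats, and the dr = 0.02 mm transport
grid. These sizes are stated inline in each test.

## Known limitations

- Serial staging: no bubble-induced convection during infusion, no
  feedback of lysis on transport coefficients, PAI-1 not depleted.
- 2D: bubbles are disks, transport is in-plane; volumetric exposure
  schemes and out-of-plane losses are not represented.
- Gaussian focal model: no side lobes or pre-focal structure; ablation
  zones are conservative relative to a measured field.
- Single-scale (per composition) synthetic texture; quantitative
  cohort statistics (correlation coefficients, pulse counts to plateau,
  box-plot spreads) depend on real-section texture and are out of scope.
- Pulse independence assumes slow pulsing; clinical rates produce
  smaller lesions than this model predicts.
- Endogenous plasminogen activators (~1% effect) are neglected.
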