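# Methods

`stentmra` models an in-vitro bench experiment: a metal vascular stent
deployed in a plastic tube filled with 25 mmol/L Gd-DTPA solution,
embedded in a muscle-like gel block, imaged at 1.5 T with a clinical 3D
T1-weighted spoiled gradient-echo MRA protocol, and scored for how well
the stented lumen remains visible. The package has two surfaces: an exact
arithmetic surface (measurement tables → scores → classification) and a
physics simulation surface (phantom → image → measurements). This note
documents the models, the defaults, and what each surface can and cannot
show.

## Phantom geometry

The phantom is rasterized onto a fine isotropic grid (default 0.25 mm;
the test suite and acceptance script use 0.5 mm to keep grids near
40×40×90) with four labels: gel, tube wall, lumen fluid, strut. The tube
axis is the z axis and is parallel to B0, as the stents were positioned
in the magnet; orientation dependence of the artifacts is out of scope.

Commercial strut patterns are proprietary, so stents are generic cages
whose artifact behaviour is steered by material parameters rather than
micro-geometry:

- **mesh / covered** — `n_helical_wires` (default 8) helix starts in each
  winding direction at pitch `length/6`, wire radius 0.1 mm, laid just
  inside the tube wall;
- **slotted_tube** — circumferential rings every `length/6` connected by
  `n_helical_wires` axial bridge bars. Rings plus symmetric bar angles
  make the cage mirror-symmetric about the axis, a property the tests
  exploit;
- **coil** — a single-handed helix family.

A stent nominally wider than its tube is clamped to the tube bore with a
warning (constrained expansion; this is how the one 6 mm stent in a 5 mm
tube is represented). A wall thinner than one voxel is omitted with a
warning — on the 0.5 mm test grid the 0.25 mm wall of the small tubes is
therefore absent, which does not affect any lumen metric (the wall is
signal-free either way).

**Strut partial volume.** Real stent wires (0.1 mm) are far thinner than
any practical voxel. Rasterizing them as full voxels would let the grid
choice inflate the wire: a 0.5 mm voxel chain has ~8× the cross-section
of the wire it represents. Both artifact channels are therefore scaled by
the fill fraction `f = π r_strut² / voxel²`: a strut voxel keeps
`(1 − f)` of the lumen signal, and its susceptibility source is
`f · Δχ`. This conserves signal and magnetic moment per unit wire length,
so simulated measurements converge as the grid is refined instead of
drifting with voxel size.

## Signal model

Steady-state spoiled gradient echo with M0 = 1:

    S = sin(α) · (1 − E1) / (1 − E1 cos α) · exp(−TE / T2*),   E1 = exp(−TR / T1)

with the study protocol TR = 3.4 ms, TE = 1.65 ms, α = 30°, 1 mm
isotropic acquisition voxels reconstructed to 0.55 mm, at 1.5 T. Tissue
parameters:

| parameter | default | rationale |
|---|---|---|
| lumen T1 | from 1/T1 = 1/T1_water + r1·C | fast-exchange relaxivity; C = 25 mmol/L, r1 = 4.5 L/(mmol·s), T1_water = 3000 ms → T1 ≈ 8.9 ms |
| lumen T2* | 100 ms | dilute aqueous Gd solution, pre-artifact |
| gel T1 / T2* | 870 ms / 50 ms | muscle-like gel at 1.5 T |
| wall, wire | no signal | plastic and metal are MR-invisible |

At 25 mmol/L the lumen Ernst angle arccos(E1) is ≈ 47°, above the nominal
30° flip. The signal-vs-flip curve is therefore still rising at 30°,
which matters for the RF-shielding model below.

## Artifact models

**Susceptibility field.** The strut susceptibility map is convolved with
the standard Fourier-domain dipole kernel `1/3 − kz²/|k|²` (k = 0 term
zeroed, i.e. zero-mean field). Literature susceptibility differences
versus tissue are used: tantalum 190e-6, nitinol 255e-6, platinum alloy
290e-6, austenitic steel 316L in the 1e-3..1e-2 decade (5e-3 by default).
The cobalt-superalloy value (220e-6) is a calibration constant. The field
enters twice: intravoxel dephasing — fine-grid complex signals with phase
2πγ·ΔB·TE are block-averaged into acquisition voxels before taking the
magnitude — and readout misregistration, a per-voxel pull along the
frequency-encode axis of γΔB/bandwidth voxels (500 Hz/voxel default,
switchable off).

*Numerical caveat:* the sampled dipole kernel is band-limited, so at
source-voxel-scale distances its real-space response rings along the
z axis and near the magic-angle cone; pointwise agreement with the
continuum dipole field there is poor no matter the grid. Validation
therefore uses (i) a direct-space periodic dipole lattice sum, compared
in sign everywhere and in value at generic diagonal offsets, and (ii) the
closed-form uniformly-susceptible sphere (zero interior field, exterior
point dipole), which the implementation matches to ~4% in relative L2
over the exterior on a 64³ grid.

**RF (B1) shielding.** Eddy currents in the conductive cage attenuate the
transmit field in the lumen. The true B1 distribution depends on the wire
configuration and is not predictable from material alone; it is modelled
as a single per-material multiplier on the nominal flip angle inside the
stented lumen, in (0, 1.5]. Values above 1 represent the regime in which
the effective in-lumen excitation lands *nearer the Ernst angle* than the
nominal flip does, producing in-stent signal above the unstented
reference — the braided cobalt-superalloy stent in the study reads 117%.
With lumen T1 ≈ 8.9 ms the simulated ratio is capped at ≈ 112% (the Ernst
maximum), so the simulator reproduces the over-signal regime
qualitatively, not that exact figure. Shielding defaults per material
(tantalum 0.95, nitinol 0.80, 316L 0.45, platinum-iridium 0.25,
cobalt-superalloy 1.45, covered 1.10) are calibration constants chosen
once so the simulated material groups order as the phantom measurements
do; they are not measured quantities.

**Noise.** Complex Gaussian noise (default σ = 2% of the unstented lumen
signal per channel) is added at the acquisition grid before the magnitude
operation, giving Rician magnitude statistics; the generator is seeded,
and a fixed seed gives bit-identical images.

## Measurements

All three metrics are taken on the longitudinal mid-plane through the
tube axis, on the reconstructed 0.55 mm grid, with the unstented segments
(≥ 5 mm from either stent end, pooled) as reference:

1. **Relative signal intensity** — mean lumen signal (lumen mask eroded
   by 0.8 mm to exclude wall/strut partial volume) in the stent versus
   the reference, as an integer percent.
2. **Visible lumen diameter** — per axial position, the longest
   contiguous run of lumen-line pixels at or above 50% of the reference
   lumen mean (the full-width-half-maximum convention; the visibility
   threshold is a declared parameter, not a measured property of the
   original study). The denominator is *measured* on the reference
   segment by the same procedure, so an artifact-free stent scores
   exactly 100; a position with no pixel above threshold scores 0 — the
   signal-truncation pattern. The minimum and maximum over the stent are
   reported as integer percents.
3. **Homogeneity** — population SD over mean of a 120-pixel rectangular
   ROI centred in the stented lumen (width = min(lumen width − 2, 8)
   pixels reduced to the largest divisor of 120, length to reach the
   count), reported to two decimals.

Reporting precision (integers, two decimals) is part of the contract:
grading consumes the rounded values, which makes regrading a published
table exact.

## Grading

Fixed thresholds map each category to 1/2/3 points with boundary values
in the middle band: signal intensity < 40 / 40–60 / > 60; visible lumen
< 40 / 40–70 / > 70; SD/mean ≥ 0.4 / [0.1, 0.4) / < 0.1. The sum (3–9)
classifies 3–4 poor, 5–7 intermediate, 8–9 good. Regrading the packaged
22-stent table reproduces 65 of the 66 printed category scores — one
printed lumen score (38%, printed as intermediate) disagrees with its own
stated rule — and all 22 printed overall classes; two printed overall
sums are internally inconsistent in the source table (one downstream of
the category anomaly, one a plain addition error against its own printed
category scores) and are pinned as such in the tests rather than
special-cased in the rules.

## What the synthetic surface does and does not show

The generator emulates: static Gd-filled lumens (no flow — appropriate
for a contrast-enhanced protocol), uniform receive field (no coil
correction), generic strut cages, and the two artifact channels above. It
does **not** emulate: real per-product cell geometry, solved eddy-current
B1 maps, k-space sampling/Gibbs behaviour beyond spline resampling,
parallel-imaging effects, or 3 T. Consequently, passing simulator tests
demonstrates the pipeline's measurement and grading behaviour under
controlled artifact severities — not that any particular commercial stent
would reproduce its printed row. Per-stent agreement with the published
measurements is established only on the arithmetic surface.

A further caveat: at the study's TE the near-strut phase is already
beyond 2π for the stent alloys, so homogeneity is not strictly monotone
in Δχ at full precision (third-decimal oscillation); monotonicity holds
at the two-decimal reporting precision on the test grid, and strongly
into the steel regime. The visible-diameter and voxel-fraction responses
are monotone as tested.

## Problem sizes and tolerances

Tests and the acceptance script simulate a 7 mm tube with a 20 mm mesh
stent on a 0.5 mm fine grid (≈ 40×40×88 fine voxels, ≈ 31×31×80
reconstructed), the package's standard small-phantom configuration; the
library default for production use is 0.25 mm. Artifact-free identity is
asserted at ±1 percentage point (spline resampling next to signal-free
wires legitimately perturbs the ratio by ~1%); the dipole-kernel oracles
at 5% relative error; noise recovery at ±0.01 on SD/mean.
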