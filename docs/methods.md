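# Methods

## The measurement problem

Coronary endothelial function (CEF) is assessed from *relative* changes in a
coronary artery's lumen cross-sectional area (CSA) in response to an
endothelium-dependent stressor; healthy proximal segments dilate by roughly
10–25%.  Whether an imaging protocol can support that measurement depends on
how small a true CSA difference it can resolve.  `csaphantom` implements the
standard in-vitro answer to that question: a drilled resolution phantom with
finely laddered hole sizes, repeated automated CSA measurements, and a
statistical limit of detection.

## Phantom model

The phantom is a 10-cm-diameter, 2-cm-thick PMMA block with 110 holes
drilled perpendicular to its faces: 22 diameters from 3.00 mm to 3.42 mm in
0.02-mm steps, 5 replicate holes per diameter.  Adjacent drilled CSAs differ
by ≈ 0.095 mm² at the small end (1.3% of the 3-mm lumen area of 7.069 mm²)
and ≈ 0.107 mm² at the large end.

Hole *positions* are nuisance parameters — no metric depends on them — so
`build_layout` places holes by seeded sampling of distinct sites on a
regular grid whose pitch equals the minimum spacing (default 6 mm, margin
4 mm).  Distinct grid sites can never collide, so feasibility reduces to a
site count; fewer than 110 admissible sites raises "layout infeasible".
Drilling tolerance (−0/+0.004 mm, ~0.1% of diameter) is ignored; nominal
diameters are exact ground truth.  The block is modelled as a 2-D
cross-section: holes are perfectly perpendicular, so sections/frames share
one geometry and differ only in noise.

## Image formation

Both simulators share a first-order imaging chain:

1. **coverage field** — per-pixel area fraction inside any hole,
   computed by `supersample²` subsampling (default 8², error ≪ 0.1% of a
   hole area);
2. **system PSF** — isotropic Gaussian blur, FWHM 0.6 mm (CT) / 0.8 mm
   (MR) by default.  These values are configurable and deliberately *not*
   treated as physical truth: they control the FWHM segmentation bias and
   are swept in tests;
3. **motion blur** (optional) — convolution with the occupancy kernel of
   the rigid sinusoidal displacement (below);
4. **contrast and noise** — modality-specific.

**CT.**  Pixels are 0.39 mm, sections 0.625 mm (or 5 mm, formed by
averaging 8 contiguous 0.625-mm noise realizations, SD/√8).  Lumen contrast
is a lookup over (iodine concentration, tube potential): ΔHU =
170/260/330/390 at 120 kVp and 250/370/460/560 at 100 kVp for 3/4/5/6%
iodine, over a PMMA background of 120 HU.  Noise is stationary Gaussian with

    σ = σ_ref · √(20 mGy / CTDIvol) · f_kVp · f_ASiR-V,

with σ_ref = 18 HU at 20 mGy / 120 kVp / 0% reconstruction strength,
f_kVp = 1.12 at 100 kVp, and iterative-reconstruction factors 1.00 / 0.70 /
0.40 at 0 / 50 / 90% strength.  σ_ref and f_kVp were fixed once so that the
simulated SNR anchors match the study conditions (≈ 85 at the optimal
6%/20 mGy/100 kVp/90% condition; ≈ 46 at the lowest concentration).
Iterative reconstruction is a pure noise-SD multiplier: noise-texture and
resolution effects of real reconstruction algorithms are out of scope, and
real CT noise is spatially correlated while ours is white — the
background-SD noise definition used throughout is insensitive to that
correlation structure at ROI scale, but this remains a stated limitation.

**MR.**  Pixels are 0.625 mm.  PMMA has no measurable MR signal, so the
background is exactly zero before noise; the lumen signal equals the target
SNR of the gadolinium concentration against unit-SD Rician magnitude noise
(`|S + n₁ + i·n₂|`).  The concentration → SNR map is a configuration table
(defaults 8, 22, 35, 45, 52, 64, 70, 73.5 for 0.00–1.66 mmol/L), anchored
at ≈ 22 for 0.17 mmol/L and ≈ 73.5 at the top; no spoiled-GRE signal
equation is fitted because no relaxivity parameters are specified for the
doped water.  Radial k-space acquisition and regridding are not simulated;
the motion effect of the segmented acquisition enters through the 95-ms
per-heartbeat window kernel, with an optional Gaussian beat-to-beat
repositioning jitter (default 0, reflecting < 1 mm repositioning
precision).

**Motion.**  The rigid displacement is x(t) = A sin(2πt/T) with A = 15 mm
and T = 1 s (60 bpm, 30 mm peak-to-peak — the quoted "maximum displacement
of 3 cm" is read as peak-to-peak, consistent with A = 1.5 cm in the
formula).  Blur is the normalized occupancy histogram of x(t) over the
acquisition window centered at the excursion extreme t′ = T/4, binned at
the pixel pitch, splatted along an arbitrary motion axis with bilinear
deposition.  The kernel has unit mass, so noiseless total excess intensity
is conserved under motion (verified to 0.5%).

The acquisition windows come from the protocol: half the gantry revolution
for CT (0.28 s → 0.14 s) and views-per-segment × TR for segmented cine MR
(19 × 5 ms → 95 ms).  The closed-form worst-case in-window displacement

    Δx = A·max |sin(ω(t′ ± T_w/2)) − sin(ωt′)|

evaluates to 1.4276 mm (CT) and 0.6631 mm (MR); quoted one-decimal figures
are truncated (1.4 / 0.6 mm) — a truncated figure never overstates how well
a protocol freezes motion, and `format_displacement_mm` makes that
convention explicit.  The kernel support agrees with Δx within one pixel
for all tested protocols.

## FWHM segmentation

Each hole is found in two stages: a global rigid shift estimated by
normalized cross-correlation of the noiseless hole template with the mean
image (failure → "phantom not found"), then a per-hole intensity centroid in
a window of radius one diameter (local contrast below 3× the background
noise SD → hole excluded and logged).

Segmentation applies the full-width-at-half-maximum criterion per hole and
section:

* peak = mean of the top decile of intensities within 0.5 mm of the center
  (robust to single-pixel noise, insensitive to the exact core size);
* background = median in the annulus [1.5, 2.5] × r_max (r_max = 1.71 mm,
  the largest drilled radius; the median tolerates a neighboring hole's
  blurred tail clipping the annulus);
* half-max level = background + (peak − background)/2;
* contour = marching-squares iso-contour at that level.  The contour is
  extracted on a 3× cubic-spline-refined grid whose coordinates map back
  exactly to the pixel grid; this keeps the polygon-inscription error of
  the curved boundary below ~0.5%, against a no-contour oracle that
  thresholds a 20×-supersampled rendering of the same image-formation
  model.  A pixel exactly at the level counts as *below* it (half-open
  convention).  The unique closed contour enclosing the center is taken;
  several enclosing contours → innermost, with a warning; no closed
  enclosing contour → "segmentation failed (low contrast)" or, when the
  above-level region runs off the window, "window too small".

CSA is the shoelace area of the sub-pixel polygon, perimeter the polyline
length, circularity 4πA/L² (≤ 1 by the isoperimetric inequality; the raw
polygon perimeter is used without smoothing, so circularity slightly
underestimates the continuum value).  The FWHM rule is exactly invariant
under affine intensity rescaling, so contours are comparable across
modalities and contrast levels.  Optional light pre-smoothing (Gaussian,
σ in pixels) is exposed but off by default: image interpolation is known to
worsen FWHM underestimation, so it is a flag, not an assumption.

**Known bias.**  With a Gaussian PSF of SD σ_psf, the half-max boundary of
a disk of radius R sits inward by ≈ σ²/2R (σ² including the pixel-aperture
contribution p²/12), so CSA is underestimated by ≈ π·σ² — about −0.32 mm²
(−4.5%) at CT defaults, constant across the ladder, which is why the
regression slope of measured vs drilled CSA stays near unity (measured
1.004 noiseless) while the intercept absorbs the bias.  The bias grows with
PSF width (directional test) and its sign matches the systematic FWHM
underestimation reported for this criterion in the literature.

## Metrics

With valid measurements grouped by nominal diameter (100 per diameter at 20
thin sections, 15 at three 5-mm sections):

* **accuracy** — per-diameter bias mean(measured) − nominal, summarized as
  mean ± SD across the 22 diameters;
* **precision** — per-diameter sample SD (n−1), summarized likewise;
  singleton diameters are excluded with a warning;
* **AUC** — Mann-Whitney probability P(high > low) + ½P(=), computed from
  ranks; ties count one half; antisymmetry auc(x,y) + auc(y,x) = 1 holds
  exactly;
* **LOD** — for each reference diameter dᵢ, the smallest *nominal* CSA
  difference such that the pair and every larger difference from the same
  reference reach AUC ≥ 0.95 (monotone closure).  A reference whose largest
  available difference fails the threshold has no LOD; if that happens for
  every reference the condition is reported "undetectable".  The summary is
  mean ± SD over references with a defined LOD plus the undefined fraction.
  Nominal differences index the LOD because the question is posed against
  known drilled ground truth.  Diameters with under 50% valid measurements
  are dropped as unusable.  No multiple-testing correction is applied
  across the 231 pairs.  LOD is also expressed relative to the 3-mm lumen:
  % = 100·Δ/(π·1.5²), so 0.16 / 0.52 / 0.81 mm² ↔ 2.3 / 7.4 / 11.5%;
* **SNR** — mean lumen-core intensity (0.5-mm-radius disks at the hole
  centers) over the background-ROI SD per section.  For MR magnitude
  images the signal-free ROI's SD is Rayleigh-distributed and is divided by
  √(2 − π/2) to recover the channel noise SD, which makes the measured SNR
  agree with the generator's target (round-trip within a few %);
* **regression** — OLS of measured on nominal CSA (slope, intercept, r²).

The noise-measurement ROI is placed in a corner of the field of view,
outside the hole pattern and clear of every hole dilated by 3× the PSF
FWHM; the simulated background is stationary, so the corner is
statistically equivalent to any hole-free interior region.

## Misalignment and dose arithmetic

A plane tilted θ from the perpendicular cross-section cuts an ellipse of
area CSA/cos θ: fractional error 1/cos θ − 1 (≈ θ²/2 for small angles;
≈ 3% at 14°).  Segmented cine needs ⌈radial views / views per segment⌉
heartbeats (⌈247/19⌉ = 13).  Reaching a dose D in an exposure t at
normalized dose coefficient nCTDI requires current D/(nCTDI·t): 20 mGy in a
0.14-s half-scan at 0.1 mGy/mAs needs ≈ 1.43 A, beyond clinical tubes.

## Problem sizes and numerical choices

Defaults simulate 20 sections/frames per condition (110 × 20 = 2200
measurements); the test suite's noisy sweeps use 8–20 sections per
condition, which keeps the full suite under a minute on one CPU while
leaving per-diameter sampling (≥ 40 measurements) ample for the
directional comparisons it makes.  All random draws go through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
stacks, tables and CSVs.  Degenerate inputs are defined errors rather than
NaNs: empty tables, singleton diameters, zero background SD (noiseless SNR),
windows longer than the cardiac period, unknown contrast entries.

## What passing tests do and do not show

The generator reproduces the *first-order* statistics the metric suite
consumes — contrast levels, √dose noise scaling, reconstruction-strength
noise reduction, Rician background statistics, window-limited motion blur —
under which the pipeline's accuracy, precision and LOD respond to contrast,
dose and motion in the directions expected of the real experiment, and the
noiseless regression slope falls in the unity band.  It does not model
correlated CT noise texture, radial-undersampling artifacts, beam
hardening, partial-volume effects of oblique vessels, or scanner-specific
detectability, so absolute LOD values from the simulation (e.g.
≈ 0.13 mm² at the optimal CT condition) characterize the synthetic
conditions only and are expected to be better than hardware results; they
are not comparable to scanner measurements.  At the MR pixel size
(0.625 mm) the per-hole discretization bias narrows some adjacent-diameter
mean gaps to ≈ 0.03 mm², so strict ordering of all 22 mean CSAs at SNR ≈ 50
is borderline with 100 measurements per diameter; ordering is strict
noiselessly at both pixel sizes and at SNR ≳ 60 on the CT grid.
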