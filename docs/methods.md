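# Methods

`seedoct` stages seed germination nondestructively from three observation
channels — spectral-domain OCT cross-sections, camera photographs, and
gravimetric weight series — and validates the image-derived measures against
the weight gold standard. Because no public raw data exist for this kind of
bench experiment, the package pairs every estimator with a forward model
(the phantom generator) whose internal state is recorded exactly, so the
whole chain is testable by parameter recovery.

## SD-OCT forward model and reconstruction

A reflector at optical depth `z` imprints a fringe `cos(2kz)` on the source
spectrum (`k = 2π/λ`). The synthetic spectrometer frame is

```
I(λ) = G(λ) · (1 + Σ_i 2√(R_ref R_i) cos(2 k z_i)) + ε
```

with a Gaussian envelope `G` (840 nm centre, 50 nm FWHM), sampled on a
uniform wavelength grid of 1024 × 0.09 nm pixels, plus optional additive
detector noise. Reconstruction is the standard SD-OCT chain: subtract a
slowly varying background (uniform filter, width n/16 — exact for a
constant frame), cubic-spline resample onto a uniform wavenumber grid, Hann
window, zero-pad 1024 → 2048, inverse FFT, keep 1024 one-sided magnitude
bins, log-compress with a floor 80 dB below the frame maximum. Retaining
1024 bins after 2× zero-padding matches the 1024-pixel depth axis of the
printed B-scan geometry.

Closed forms: axial resolution `(2 ln2/π)·λ0²/Δλ/n` (6.23 μm in air for the
defaults) and maximum imaging depth `λ0²/(4δλ)` (1.96 mm). The B-scan axis
metadata uses 2.2 mm as the nominal depth extent; the formula value is what
`max_imaging_depth` reports, and the two are deliberately not reconciled —
the nominal extent is treated as instrument metadata, not a derived
quantity.

## Phantom geometry

The seed occupies the central 90% of a 6 mm scan. The testa surface is a
gentle convex arc (apex 350 μm, 10 μm/mm² curvature). The coat interface
sits at optical distance `thickness × RI` (RI = 1.42) below the surface.
The physical thickness time course is a monotone PCHIP through the 3-hourly
reference table (112 μm at 3 h → 197 μm at 36 h), anchored at 100 μm at
t = 0 (continuing the early slope backwards — the coat imbibes from the
moment of soaking) and held flat after 36 h. Lateral unevenness is a
zero-mean, unit-sd low-frequency random profile per seed, scaled by a PCHIP
through the per-time-point spread of the same table, so the simulated
spread peaks over 9–15 h and contracts to a few μm after 27 h.

Events (defaults): surface wrinkle 5 h (camera only), cotyledon layers 6 h
(flank regions, 250 μm below the interface), radicle 13 h 40 min (central
blob 350 μm below the interface, amplitude capped at 0.9× the surface
reflectivity so the new echo never exceeds the first peak), coat crack 31 h
(200 μm wide; both coat boundaries displaced 40 μm deeper — ≥ 5 axial
pixels — with halved intensity). Displacing both boundaries keeps the true
thickness map intact inside the crack. Features appear at the first frame
at or after their event time.

Rendering places a Gaussian axial line profile (σ from the source's axial
resolution) per layer per column, attenuated by `exp(−2 μ Δz)` (μ = 0.5/mm
through the coat), then applies multiplicative exponential-intensity
speckle of contrast 0.5 per pixel before log compression. Speckle is drawn
independently per pixel (no PSF-scale correlation) — adequate for testing
peak-based estimators, optimistic for texture-based ones. The surface
curvature default is deliberately small: with 60 picks over a 5.4 mm span,
a steeper arc alone would step more than 5 axial pixels between adjacent
picks at the flanks, which is structurally indistinguishable from the crack
criterion.

The bench protocol being emulated sets the defaults: one B-scan every 10 min
for 40 h (240 time points), weight every 30 min for the first 10 h then
every 5 h, 10-seed cohorts with ±45 min event jitter, ±2% thickness
scaling, ±5% dry weight and ±3% initial diameter.

## Weight and camera models

Weight follows the classic triphasic curve: saturating imbibition
`W0(1 + u(1 − e^{−t/τ1}))` until the radicle event, a shallow linear lag
plateau until the crack event, then renewed saturating uptake; multiplied
by lognormal measurement noise (sd 0.5%). τ1 = 10 h matches the
coat-thickening timescale implied by the thickness table — the two series
are meant to co-vary, which is exactly the property the correlation
validation tests. Defaults: W0 = 0.35 g, u = 0.45, plateau 1 mg/h,
phase-III gain 50 mg.

The camera renders an antialiased bright disc (equivalent diameter
4.2 → 5.4 mm, saturating with τ = 8 h) over a dark background with a
water-surface shadow band at 70% image height; the seed occludes the
shadow. After the wrinkle event the boundary radius is modulated
sinusoidally (12 lobes, 50 μm amplitude growing 4 μm/h). Pixel scale is
11/644 mm/px, isotropic (the nominal 644 × 482 px over an 11 × 11 mm field
implies anisotropic pixels; square pixels are assumed and the scale is
configurable).

## Estimators

**Thickness.** The seed span is the widest contiguous run of columns whose
peak exceeds the image median by 10 dB. At 60 equally spaced positions the
(speckle-smoothed, σ = 1.5 px) depth profile is peak-picked (prominence
≥ 6 dB, separation ≥ the axial resolution, three-point parabolic subpixel
refinement): first peak = surface, next = interface. Both point sets are
fitted with PCHIP (shape-preserving, interpolating); thickness is the
vertical distance between the fits divided by the RI. Vertical rather than
surface-normal distance is a convention, adequate for gently curved
surfaces. Summaries use sample sd (n−1), linear-interpolation quartiles,
and whiskers at the most extreme data within 2×IQR of the quartiles.

**Indicators.** A "new subsurface peak" means the count of peaks deeper
and weaker than the surface peak exceeds the first frame's count. Radicle:
first such frame in the 20-average central profile persisting ≥ 2
consecutive frames. Cotyledon: first frame by which *both* flank profiles
(25% and 75% of the span) have persistently gained a peak; one missing
flank degrades to single-flank with a recorded warning. Crack: ≥ 3
consecutive picks with no surface, or an inter-pick surface jump strictly
exceeding 5 axial pixels, persisting 2 frames. Wrinkle (camera): boundary
roughness (sd of radial residuals from the best-fit circle / radius)
strictly above max(baseline mean + 3 sd, 4·10⁻³), persisting 2 frames; the
absolute floor exists because a noise-free baseline has sd ≈ 0 and the bare
rule would fire on rasterization jitter (~2·10⁻³). The radicle and crack
onsets split the record into phases I/II/III; onset resolution is the
acquisition cadence.

**Correlation.** Series are linearly interpolated onto the coarser
(gravimetric) grid inside the overlapping span; the Pearson coefficient is
computed from its defining sums, and |r| > 0.95 is the validation flag.
Cohort-level r uses cohort means (per-seed values are also available from
the pipeline outputs).

## Numerical choices and degenerate inputs

Log floors (−80 dB relative to frame maximum) avoid log(0); constant
profiles yield empty peak sets rather than errors; boundary fits require
≥ 4 valid picks; summaries require ≥ 5 values; crossing boundary curves are
flagged, never clipped; a coat thinner than the axial resolution raises an
"unresolvable" error from the quick central estimator. All randomness flows
from a single integer seed through per-frame seed sequences, so any frame
is bit-reproducible independent of access order, and full runs are
byte-deterministic.

## Problem sizes

Tests and the acceptance script use the full default B-scan geometry
(1024 × 1000). Monte-Carlo sizes chosen for the suite: 20 speckle
realizations per tabulated time point for thickness recovery, 20 randomized
phantoms (plus 5 with events disabled) for indicator recovery, 10-seed
cohorts for the correlation checks; narrower-width phantoms (300 columns)
are used in some unit-level Monte-Carlo tests.

## What passing does and does not show

Recovery on these phantoms demonstrates that the estimators are unbiased
and event-exact under the modelled conditions: Gaussian layer echoes,
uncorrelated exponential speckle, smooth boundaries, step-like event
onsets. Real scans add correlated speckle, sensitivity roll-off with depth,
refraction at the curved surface, gradual event onsets and operator
variability in point marking — none of which are modelled (no Monte-Carlo
light transport, polarization, or dispersion). The measured correlation
values on real seeds are therefore not reproducible here; the package
instead shows the pipeline reproduces them structurally (|r| ≥ 0.95 on a
cohort built to co-vary) and recovers known ground truth to within the
stated tolerances.
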