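# Methods

## The measurement model

An FT-IR absorbance spectrum of an RNA film is modelled as a sum of
pseudo-Voigt bands plus a slow baseline drift and white acquisition noise:

    A(ν; f) = Σ_k s_k(f) · a_k · pV(ν; c_k, w_k, η_k) + d(ν) + ε(ν)

where `pV = η·Lorentzian + (1−η)·Gaussian` (unit peak height), `f ∈ [0,1]`
is the global methylation fraction and the scaling `s_k(f)` is 1 for
methylation-independent bands, `f` for the CH₃ marker bands introduced by
the methyl moiety, and `1−f` for bands attenuated by methylation (the N–H
stretching contribution, since N6-methylation converts the adenine NH₂ to
NH). The model is linear in `f`, which is what justifies the univariate
linear calibration downstream and makes an integer v/v mixture of the 0 %
and 100 % stocks equivalent to a sample generated directly at the mixed
fraction.

CD spectra use the same band machinery with signed amplitudes (mdeg);
each experimental condition (unmethylated/methylated synthetic oligo,
cellular control, writer-enzyme knockdowns, stimulus treatments) is a
separate catalogue encoding the A-form signature and its reported
perturbations (e.g. the 267 → 266 nm shift with amplitude gain on
methylation; the roughly halved 209.7 nm trough after METTL3 knockdown).

### Band parameter defaults and why

Band *positions* are empirical constants for RNA. Widths, amplitudes and
shapes are not instrument-resolved for this system, so they are package
defaults chosen once on physical grounds:

* FWHM 25 cm⁻¹ in the C–H stretching region, 20 cm⁻¹ for generic
  fingerprint bands, 250 cm⁻¹ for the broad O–H/N–H envelope, 8–10 nm for
  CD bands.
* FWHM 10 cm⁻¹ for the CH₂/CH₃ *bending* bands and the sugar-backbone
  markers. Two constraints force the narrower width: the 1468 cm⁻¹ CH₂
  bend and 1478 cm⁻¹ CH₃ bend must merge into a single absorbance maximum
  yet separate into two minima in the 9-point Savitzky–Golay second
  derivative (at 2 cm⁻¹ spacing this requires FWHM ≈ 10; at 12 the
  second-derivative minima also merge), and the 880/865 cm⁻¹ sugar pair
  (15 cm⁻¹ apart) must keep distinct maxima.
* Amplitudes: strongest base band (≈1650 cm⁻¹ C=O/C=N envelope) = 1.0;
  the strong CH₃ markers at full methylation ≈ 30 % of it (0.30 at 2984,
  0.24 at 1478), their symmetric partners deliberately weak (0.10 at 2883,
  0.08 at 1363) so the marker-quality ordering seen in practice
  (stretch > symmetric stretch, asym bend > sym bend) emerges from the
  band model rather than from tuned noise.
* Shape: pseudo-Voigt η = 0.1 for methylation-independent bands
  (condensed-phase bands are near-Gaussian with mild tails). The
  methylation-*dependent* bands are pure Gaussian (η = 0): the equal-area
  normalisation window 1750–1513 cm⁻¹ is defined as methylation
  independent, and Lorentzian tails of the 1478/1488 bands (and of the
  complement N–H envelope) would leak ~10⁻⁴ relative area into it, making
  the normalisation scale weakly f-dependent and the noise-free
  calibration inexact.
* Default drift: quadratic, ≤ 5 % of the strongest band; noise:
  i.i.d. Gaussian per point with SD = `noise_sd_rel` × the largest
  catalogue amplitude, default 0.5 %; a seed is mandatory whenever noise
  is on, and identical configuration + seed reproduces spectra
  bit-identically.
* Grids: 4000→800 cm⁻¹ at 2 cm⁻¹ (stored descending, the plotting
  convention of the field); CD 190→350 nm at 0.1 nm, ascending.
* The cellular catalogue shifts the CH₃ markers to 2949 (broad,
  FWHM 35)/2883/1488/1359 cm⁻¹; knockdown samples are emulated with an
  effective fraction of 0.8× the control, matching the magnitude of
  global m⁶A loss reported for METTL3 silencing.

## Preprocessing conventions

* **Baseline**: straight-line interpolation through the spectrum's values
  at 13 fixed anchor wavenumbers (3970 … 801 cm⁻¹), subtracted. Anchors
  snap to the nearest grid point (the 2 cm⁻¹ grid holds only even
  wavenumbers), which makes the operation reproducible and exactly
  idempotent; beyond the outermost anchors the nearest segment is
  extended linearly.
* **Normalisation**: |absorbance| trapezoid area over 1750–1513 cm⁻¹
  scaled to 1.0 (only "equal area" is meaningful; the target is a unit
  choice, so all downstream intensities are in normalized units). The
  1510 baseline anchor and the 1513 normalisation limit are kept as two
  independent constants, as specified.
* **Averaging**: a replicate is the pointwise mean of its (default 4)
  sequential scans; averaging follows baseline correction and
  normalisation, then the second derivative is taken from the average.
* **Savitzky–Golay**: window 9 points, polynomial order 2 (the minimum
  supporting a second derivative and the common vendor default), scaled
  by the grid step so units are per (cm⁻¹)ᵒʳᵈᵉʳ (per nm for CD); edges
  are handled by the polynomial fit on the truncated window; odd-order
  derivatives are sign-corrected for the descending FT-IR axis.
* **Dryness QC**: the integrated O–H stretch (4000–3000 cm⁻¹); a film
  counts as dry when the last four sequential areas vary by < 2 %.
* Processing states (`raw → baseline_corrected → normalized →
  derivative2`) are enforced and only advance forward; out-of-order
  application raises instead of silently recomputing.

## R-method intensity and its apex

The intensity of a marker band is its height above the chord drawn
between the spectrum's values at the grid points nearest the window's two
frequency limits (3012–2865 cm⁻¹ for both CH₃ stretches, 1513–1437 for
the asymmetric bend, 1436–1344 for the symmetric bend). Three apex
conventions are provided:

* `auto` (default): the local maximum nearest the window's target
  wavenumber, searched within ±8 cm⁻¹ of it; if none exists that close,
  the reading is taken at the target grid point. This emulates a peak
  pick at the defined marker position. An unrestricted in-window search
  is wrong twice over: the two CH₃ stretches share one chord window (a
  global maximum would read identically for both), and at low
  methylation it hops to the 1468 cm⁻¹ CH₂ bend, bending the 1478
  response into a strongly nonlinear curve, contrary to the linear
  response this readout is meant to capture.
* `max`: the in-window global maximum (useful for "what is the strongest
  feature in this window" questions, e.g. confirming that the
  unmethylated sample's maximum sits at 1468, not 1478).
* `fixed`: always read at the target grid point. With fixed positions
  the noise-free mixture series is *exactly* linear (R² = 1 to machine
  precision); with `auto` the apex can hop one grid point between
  levels, leaving 1 − R² ~ 10⁻⁶.

Negative intensities (peak below the chord) are returned unclipped with a
`below_baseline` flag.

Band *positions* are read from the second derivative as the most negative
local minimum in the window (ties toward the lower wavenumber), with a
floor of 10⁻¹⁵ × the spectrum's largest |second derivative| so that
floating-point dust on featureless segments is not mistaken for a band;
an empty result raises "absent band".

## Calibration, inverse prediction, comparison

Ordinary least squares of intensity on methylation % (n ≥ 3, non-degenerate
design); R² is the squared Pearson correlation; the residual SD uses n − 2
degrees of freedom. A zero-variance response yields slope 0 with R²
flagged NaN rather than an error. Inverse prediction reports
x̂ = (I − a)/b with the first-order standard error
(s/|b|)·√(1 + 1/n + (x̂ − x̄)²/Sₓₓ) and an out-of-range flag outside
[0, 100] (values are not clipped).

Group comparison reads every marker in both groups, reports absolute and
relative differences (control in the denominator), a two-tailed Welch
t-test when both groups have ≥ 3 replicates (variances are not assumed
equal; no multiple-testing correction across the four markers — the
report says so), and an overall direction by marker majority with ties
called "no-change". When both groups' readings are literally constant the
t-test is undefined: identical means report p = 1, otherwise no p.

## CD peak inventory and matching

Peaks are signed extrema exceeding a prominence threshold (default 2 % of
the spectrum's largest |ellipticity| — small enough to keep the weak
222-nm shoulder, large enough to reject generator-level noise), positions
refined by the Savitzky–Golay first-derivative zero crossing within one
grid step. Condition comparisons match inventories greedily by nearest
position within 6 nm (larger than any reported methylation-induced shift,
smaller than the inter-peak spacing); Δposition and Δamplitude are test −
reference, so swapping arguments negates them. No secondary-structure
fraction estimation is attempted — the tool reports empirical signatures
only.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis relies on: band
positions and their methylation dependence, overlap between neighbouring
bands (the 1363 cm⁻¹ window deliberately shares its low-wavenumber chord
endpoint with a constant backbone band at 1340 cm⁻¹, degrading that
marker's calibration the way weak overlapped bands degrade in practice),
replicate noise, baseline drift, and the CD condition signatures. It does
not model water-vapour/CO₂ lines, ATR penetration-depth dispersion,
scattering artefacts, detector nonlinearity, or any quantum-chemical
prediction of frequencies — band positions are empirical constants.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the *pipeline* under the stated noise model, not instrument
performance on real films.

Problem sizes used by the test suite: 1601-point FT-IR and CD grids; the
statistical suites run 200 seeded simulations of the 5-level mixture
series (bias of inverse prediction ≤ 2 percentage points at 1 % noise)
and 200 seeded control-vs-knockdown comparisons (majority direction
correct in ≥ 95 % of runs).

## Known limitations

* The calibration is univariate by design; no PLS/PCR chemometrics.
* JCAMP-DX support covers the `(X++(Y..Y))` AFFN dialect read-only.
* CD concentrations are metadata only; no molar-ellipticity conversion.
* `find_band_position` and the R-method apex can disagree for strongly
  overlapped bands; both are reported deliberately.
* The dryness predicate needs at least four sequential areas and is a
  heuristic, not a physical drying model.
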