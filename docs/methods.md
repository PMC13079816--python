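# Methods

## What the package computes

`nbviability` quantifies nanobubble cytotoxicity assays on iPSC-derived
neural cultures from fluorescence micrographs of Hoechst-stained nuclei, and
implements the nanoparticle-tracking physics used to characterise the
nanobubbles themselves. The chain is:

1. nuclei detection by overlapping-ROI scanning of each micrograph;
2. live/dead classification of each nucleus by fluorescence intensity (FI),
   live iff FI < 100 a.u. (strict);
3. per-day count statistics: mean x̄(N) and population SD σ(N) (divisor n)
   of the per-image live counts, areal concentration x̄(N)/1.77 mm²;
4. the live cell ratio LCR(N) = conc(N)/conc(0), so LCR(0) = 1 by
   definition, with ratio-error propagation and a 3-day average summary;
5. nanoparticle tracking: MSD → diffusion coefficient → Stokes–Einstein
   diameter; multi-depth electro-osmotic correction → electrophoretic
   mobility → Smoluchowski zeta potential.

Because no imaging or tracking data are distributed with the assay, a
synthetic-data generator stands in for the microscope and the tracking
instrument; it is first-class, tested code.

## Synthetic imaging model

A field is 2048 × 2048 px at 0.65 µm/px (1.3312 mm per side, 1.77 mm² —
the divisor of the areal-concentration formula). A 1.3 µm pixel pitch, the
nominal camera value, is available through configuration; the two numbers
cannot both hold for a 1.77 mm² field on a 2048² sensor, so the geometry
that reproduces the statistics' divisor is the default.

Nuclei are isotropic Gaussian blobs (PSF σ = 2 µm) of amplitude equal to
the nucleus peak FI, on a uniform 10 a.u. background, with optional Poisson
shot noise and Gaussian read noise (default σ = 1 a.u.). Peak FIs are drawn
from two Gaussian populations — live 50 ± 15 a.u., dead 200 ± 15 a.u. —
chosen only to be cleanly separable at the 100 a.u. classification
threshold; draws crossing the threshold are rejected and redrawn, so
ground-truth labels are always recoverable from peak FI. Draws are floored
at 10 a.u. (10 % of the threshold): a Hoechst-positive nucleus is by
construction clearly visible, and an unbounded lower tail would make
arbitrarily dim, undetectable "nuclei" that no intensity-based counter
could find. All population parameters are fixture inventions, not
measurements.

Placement is uniform inside the field with a 25 µm edge margin (so a
detector restricted to fully interior ROI placements can reach every
nucleus) and an optional hard-core minimum spacing (default 15 µm, the
nucleus scale) enforced by bounded rejection sampling.

Multi-day kinetics multiply the expected live count per image
(default n₀ = 180, ≈ 100 cells/mm²) by a per-day factor g: presets
`no-nb` g = 1.3 (growth), `nb-pos` g = 0.4 and `nb-neg` g = 0.75
(decline, faster for positively charged nanobubbles). These rates are
invented to reproduce the assay's qualitative orderings, not its numbers.
Dead nuclei remain visible: a persistence fraction (default 0.5) of
cumulatively lost cells plus a 5 % spontaneous baseline. Per-image counts
are Poisson around the expectation; every stochastic call receives an
explicit seed.

What the generator does *not* emulate: uneven illumination, optical
aberrations, overlapping/touching nuclei, out-of-focus cells, debris, or
the Calcein/EthD-III channels. Passing tests therefore demonstrate the
correctness of the counting and statistics machinery on well-behaved
fields, not robustness to the full pathology of real micrographs.

## Detection

The detector scores every fully interior placement of a square,
nucleus-sized ROI (default 15 px ≈ 10 µm, stride 1 = fully overlapping) by
its background-subtracted mean intensity — an area statistic, robust to
single-pixel noise. Background defaults to the global image median, with a
tile-median option for uneven illumination. Candidates must score strictly
above the detection threshold (default 2 a.u., ≈ 20 % below the score of
the dimmest allowed nucleus and far above the background score noise).
Overlapping hits over one nucleus are collapsed by greedy non-maximum
suppression: descending score, ties broken by row-major position, a
candidate accepted iff its centre is at Chebyshev distance ≥
`min_separation_px` (default = ROI size) from every accepted centre.

Known limitations, both documented and tested: nuclei within half an ROI of
the image edge are missed (only interior placements are scored), and the
box-mean score surface has a flat top (effective width
√(σ_psf² + k²/12) ≈ 5.3 px), so the argmax localisation of a nucleus
jitters as √(noise/peak) — about ±2 px for the dimmest (10 a.u.) nuclei at
1 a.u. read noise, sub-pixel for typical nuclei. Counting accuracy is
unaffected well before localisation degrades.

Per-nucleus FI is the background-subtracted mean over a centred aperture,
clamped at zero. The standalone operation defaults to the ROI box; the
pipeline configures a 3 px aperture instead, which reads ≈ 0.93 × the peak
FI, so the 100 a.u. live/dead threshold applies on the peak-FI scale (a
nucleus-sized box would average a dead nucleus's blob down to ≈ 0.25 × peak
and misclassify it as live).

## Statistics

Count summaries use the population SD (divisor n) as the assay prints it;
sample SD (n−1) is available via `ddof`. The ratio error is propagated in
two modes. The default `printed` mode evaluates the assay's formula exactly
as typeset, `sqrt((ε₁/M₁)² + (ε₂/M₂²)²)`, whose first term is
dimensionless and hence dimensionally inconsistent with an absolute error
of M₁/M₂ — the formula is reproduced faithfully rather than silently
corrected. The `standard` mode is the usual first-order expression
`(M₁/M₂)·sqrt((ε₁/M₁)² + (ε₂/M₂)²)`; Monte-Carlo resampling (10⁵ Gaussian
draws) confirms it within 5 % for relative errors up to ≈ 0.1. Beyond that
the ratio distribution's higher moments dominate (≈ 14 % discrepancy at
ε/M = 0.2), a property of the mathematics, not of the implementation, so
the property-based grid stops at 0.1. Errors are propagated from the count
means and SDs (the common field area cancels in the ratio); the 3-day
average combines the per-day errors in quadrature under a day-independence
assumption.

The two-sample comparison is the pooled-variance unpaired Student's t with
two-tailed p (df = n₁+n₂−2), via `scipy.stats.ttest_ind`; two constant
identical samples return t = 0, p = 1 by convention. Percent change is
100·(after−before)/before by default; the reversed-sign convention is
provided because a reported change below −100 % is only expressible that
way, and neither intent is guessed.

## Nanoparticle tracking

Tracks are 2-D (camera plane), so MSD(τ) = 4Dτ. MSD uses all overlapping
displacement pairs (maximal data use at the cost of inter-lag correlation);
D is a quarter of the slope of a free-intercept least-squares line through
the first 25 % of lags — the intercept absorbs static localisation noise,
and restricting the fit limits correlation bias. A negative fitted slope
clamps D to 0 with a warning. Sizing is d = k_BT/(3πηD); medium defaults
are T = 298.15 K, η = 8.9 × 10⁻⁴ Pa·s, ε_r = 78.5, all explicit
configuration (η is not auto-adjusted for T). The submicron ("ultrafine")
criterion is strict: d < 1000 nm.

The electro-osmotic correction fits a quadratic to apparent velocity
versus normalised chamber depth z ∈ [0, 1] (≥ 3 distinct depths required).
In a closed cell the net flow is zero, so the depth-averaged fitted
profile, a/3 + b/2 + c, is the particle's own electrophoretic velocity.
Any instrument's proprietary multi-depth scheme may differ; the contract
here is the stated mathematical one, tested on constructions where it is
exact. Zeta follows from Smoluchowski, ζ = µη/(ε_rε₀), sign preserved.

The Einstein-relation consistency check fits D over a 10 s window and
reports the ratio of observed to predicted MSD slope, "consistent" inside
a configurable band (default [0.5, 2]); a single 10 s track at 33 fps
estimates D to roughly ±20 %, so ensemble medians are used where a tight
ratio matters.

## Problem sizes and determinism

Default study conditions are 10 images per day over Days 0–3, full-size
2048² fields; the test suite exercises the end-to-end contracts on 512²
fields (the geometry is configuration, not code) and the counting
guarantees on 50 full-size fields. NTA recovery uses 100 particles × 300
steps at 33 fps, 20 seeds. Every stochastic stage takes an explicit seed;
pipeline stages derive their seeds from one master seed by fixed offsets,
so any stage can be rerun in isolation and reruns are byte-identical
(timestamps in the run report aside).
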