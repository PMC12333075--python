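# Methods

This note records the models, conventions and design choices behind
`peatspec`, in the order the pipeline runs.

## Spectral data model

All spectra are reflectance factors (RF) — the ratio of target-reflected
to ideal-reference-reflected radiation — on a strictly increasing
integer-nanometre grid, the 1-nm grid that ASD-type field spectrometers
interpolate to. The measurement geometry (HCRF for outdoor plot spectra,
DHRF/CCRF for integrating-sphere and laboratory spectra) is carried as
metadata but treated identically downstream: after harmonization the
pipeline deliberately refers to all of them as RF. Values slightly above
1 are physically legitimate for bright targets; the reader warns above
1.5 but never clamps, because silent clamping hides instrument problems.
Masked regions are *removed* from the grid, not flagged, so every
retained value is a real measurement and downstream code never needs a
missing-value convention.

## Harmonization

Smoothing uses Savitzky–Golay filters with a second-order polynomial and
window sizes of 15, 39 and 75 samples in the 350–1000, 1001–2000 and
2001–2500 nm segments respectively (nm and samples coincide on the 1-nm
grid); the wider SWIR windows compensate for the lower signal-to-noise of
InGaAs detectors. Segments are filtered independently, so the different
window lengths never leak across the 1000/2000 nm boundaries; the
difference relative to filtering jointly is confined to half a window on
each side of those boundaries. Within a segment, each maximal run of
contiguous 1-nm samples is filtered separately, which makes the filter
well-defined on already-masked data (it never smooths across a gap).

Segment edges are handled by fitting the order-2 polynomial to the last
full window (`scipy.signal.savgol_filter(mode="interp")`). This choice is
deliberate: it is the only standard edge treatment under which an
order-2 filter reproduces quadratic signals *exactly at the edges* as
well as in the interior, a property the test suite pins at 1e-9.
Reflection-style padding does not have this property (a mirrored
quadratic is no longer a quadratic unless its slope vanishes at the
edge).

Masking drops 350–399 nm (UV edge noise) and the three atmospheric
water-vapour bands 1330–1549, 1761–2024 and 2311–2500 nm, leaving
400–1329, 1550–1760 and 2025–2310 nm — 930 + 211 + 286 = 1427
wavelengths. Smoothing precedes masking, so structure inside a masked
band influences smoothed values within half a window of the band edge;
this matches smoothing the complete instrument record before discarding
its noisy regions, and the order is pinned by a regression test.

Leaf-level endmember replicates (adaxial sides) are averaged per species
into a single reference spectrum.

## Sentinel-2 band simulation

A band value is the SRF-weighted mean of the spectrum,
Σ srf(λ)·rf(λ) / Σ srf(λ), summed over the wavelengths actually present.
Renormalizing the SRF over the unmasked support is the only convention
that maps constant spectra to themselves when a band partially overlaps a
mask, so bands near mask edges are unbiased for flat spectra. A band
whose entire support is masked is an error naming the band — this is why
the cirrus band B10 (1375 nm, inside a water band) cannot be simulated.
B1 and B9 are excluded as 60-m bands of little use for 1-m² vegetation
plots, leaving B2–B8a, B11, B12 (centres 490…2190 nm).

The package bundles a synthetic Gaussian-SRF band set with the MSI band
centres and FWHMs near the published bandwidths, clearly labelled
synthetic; a real ESA SRF export in the documented CSV layout is a
drop-in replacement.

## Fractional cover and diversity

Cover comes from point-intercept sampling: a 1 m × 1 m frame divided
every 10 cm gives 100 cell centres; the species at each centre is
recorded (exactly one label per cell, so covers partition the plot and
sum to 100%). The estimator f̂_s = 100·count/n is binomially unbiased,
which the suite verifies over 10,000 multinomial replicates.

Shannon–Wiener H = −Σ p ln p is reported in nats (log base configurable)
and Simpson as the complement form D = 1 − Σ p², matching the common
community-ecology defaults; both are cross-checked against scikit-bio.

## Endmember selection and unmixing

A species is excluded from the endmember set only when rare on *both*
axes: present in fewer than 5 plots AND below 5% cover in the plots where
it occurs (litter counts as a species). "Cover in these plots" is judged
by the maximum over occupied plots — the inclusion-favouring reading — 
with a mean-based variant behind a flag.

Unmixing solves a_raw = argmin_{a≥0} ‖Ea − y‖₂ per plot by Lawson–Hanson
NNLS (SciPy's implementation), with no intercept and no sum-to-one
constraint; abundances are normalized post hoc, a_norm = a_raw/Σa_raw.
This mirrors the common field practice of letting the solver absorb
overall brightness differences and normalizing afterwards; a fully
constrained variant (FCLS, sum-to-one inside the solver via the
augmented-row construction) is exposed as an option. Plots whose raw
coefficients are all zero are flagged and excluded.

Zero-removal drops (plot, species) pairs whose *observed* cover is zero
from the evaluation set — per-species accuracy is judged over the plots
where the species occurs — while keeping the values in the result table
for inspection. Dropping predicted zeros instead is available behind a
flag. Metrics are computed after zero-removal.

Accuracy uses R² = 1 − SSres/SStot (negative values are meaningful: the
model is worse than predicting the mean), RMSE in percent cover, and
bias = mean(predicted − observed), so positive bias means
over-prediction.

## Wavelength R² profiles

For screening which spectral regions carry cover information, a simple
linear regression of rf(λ) on a species' cover is fitted across plots at
every retained wavelength; its R² equals the squared Pearson correlation
and lies in [0, 1] (distinct from the evaluation R² above, which can be
negative). All plots of the trophic level enter by default, zeros
included; a flag restricts to occupied plots.

## PLS diversity models

Spectra are massively collinear, so diversity is predicted by PLS1
(NIPALS): predictors centred and scaled to unit variance (ddof = 1,
toggleable), response centred, one component extracted per iteration with
deflation, coefficients mapped back to original units. Full-component PLS
on full-rank predictors reproduces the least-squares fit, and predictions
are cross-checked against scikit-learn's PLS implementation to 1e-6 on
collinear fixtures.

The component count is chosen by 10-fold cross-validation: seeded random
balanced folds, candidates 1..max, minimum PRESS (sum of squared held-out
errors), ties to the smaller count. The final model is trained on a
seeded random 70% of plots (unstratified) with CV run on the training set
only, and scored on the held-out 30%. All randomness sits behind explicit
integer seeds.

## The synthetic generator

`gen_study` emulates a two-trophic-level campaign: per-species endmember
spectra on the full 350–2500 nm grid, per-plot covers, mixed plot
spectra, and 100-point intercept grids, all deterministic under the seed.

Endmember templates are parametric: a logistic red-edge step from a
visible baseline to a NIR plateau, a Gaussian green peak at 550 nm, a
linear SWIR trend, and water-absorption dips at 1450/1940 nm scaled by a
moisture parameter, plus a seeded smooth perturbation per species.
Defaults encode the qualitative field contrasts — vascular plants with
stronger green peaks and steeper red edges than *Sphagnum* mosses, mosses
wetter (deeper dips), litter monotonically brightening through the
visible with high, dry SWIR, and the shrub *Calluna vulgaris*
intermediate toward litter — but every number is invented; the generator
imitates shapes, not measurements.

Study-level defaults: 60 plots per trophic level (the scale of a
realistic field campaign), six candidate species per level, symmetric
Dirichlet(0.6) covers with draws under 0.5% zeroed and renormalized
(producing genuinely absent species for the zero-removal path), additive
rf noise sd 0.002, log-normal per-plot-per-species brightness jitter with
sigma 0.05, and an optional shade factor (an unmodelled dark endmember)
defaulting to off. Under these conditions the mixing model is correctly
specified, so unmixing recovers per-species cover with R² ≈ 0.99 — the
test suite pins R² > 0.9 for species observed in at least 20 plots, that
noise degrades recovery monotonically, and that hyperspectral input
recovers covers at least as well as the 10-band simulation.

What the generator does *not* emulate: nonlinear/multiple-scattering
mixing, within-species spectral variability beyond a brightness scalar
and smooth jitter, multi-layer canopies, moisture gradients between
plots, and measurement-geometry differences between HCRF/DHRF/CCRF.
Passing tests therefore demonstrate the correctness of the pipeline's
computations, not field-level accuracy: on real plots the linear model is
misspecified and per-species R² is far lower and can be negative. For the
same reason the PLS diversity models score near zero (sometimes slightly
negative) test R² on the default synthetic study — composition is drawn
independently of everything else, so diversity carries only the weak
linear trace it leaves in a mixed spectrum, and the CV usually selects a
single component.

## Problem sizes and numerics

The test suite and the reproduction script run the default study (120
plots total, 1427 retained wavelengths, 10 simulated bands), 100-replicate
CV-selection simulations at n = 100 × 50, and 10,000-replicate
cover-estimator checks; the full suite completes in well under a minute
on one CPU. Numerical tolerances: SG polynomial reproduction and
round-trip I/O at 1e-9, band-resampling linearity at 1e-12, NNLS KKT and
oracle agreement at 1e-6, PLS/least-squares agreement at 1e-8.

## Known limitations

- The CSV dialect (wide spectra + sidecar metadata) is a generic target;
  adapters for particular archive layouts are the user's responsibility.
- NNLS abundances are not variance-weighted; heteroscedastic noise across
  the SWIR would argue for weighting the fit.
- The CV criterion is minimum PRESS; no one-standard-error rule is
  applied, so on noisy data the selected component count can sit one or
  two above the parsimonious choice.
- The 70/30 split is unstratified; with few plots per site the test-set
  composition can vary noticeably between seeds.
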