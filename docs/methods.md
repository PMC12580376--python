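# Methods

This note documents the models, conventions and design choices behind
`earlycrop`, in the order data flows through the package.

## Season grid and compositing

All series live on sixteen 10-day windows anchored at DOY 121 (May 1):
[121–130], …, [271–280].  Window *centres* (125.5, 135.5, …) are the abscissa
for interpolation, harmonic fitting and phenology; window *end* days
(150 … 280 for the truncation rounds) label the temporal-progression
experiment, which reconciles a first round spanning May 1–31 with 14 rounds
ending in early October.

Within a window the composite is the median of all valid observations; an
even count yields the mean of the two middle values.  Cloud-flagged optical
observations are removed before compositing (the QA flag is a single boolean
per observation — a stand-in for an operational cloud/cirrus bitmask; a
real-data adapter would map the mask bits onto it).  SAR observations are
never cloud-masked.  Empty windows are filled by linear interpolation between
the nearest observed windows in centre-DOY coordinates; leading/trailing gaps
take the nearest observed value, which avoids inventing trends outside the
observed range.  Gap filling never modifies an observed window.  A pixel with
no observed window at all cannot be filled and raises an error at the API
level; inside the temporal sweep (where very short truncated spans under
heavy cloud can produce such pixels) the pipeline substitutes the per-window
median over training pixels and records the count in the round manifest.

## Optical features (94 per pixel)

Eleven spectral parameters — six bands (Blue, Green, Red, RE2, SWIR1, SWIR2)
and five indices (EVI, LSWI, RENDVI, REPI, NDSVI) — are summarised by:

* **Statistics (66)** — min, max, population standard deviation, and the
  15/50/90th percentiles with linear interpolation between order statistics
  (NumPy's default convention).
* **Peak composites (22)** — the values of all 11 parameters at the window of
  maximum EVI ("greenest", suffix `_EVI`) and maximum LSWI ("wettest",
  suffix `_LSWI`).  Ties resolve to the earliest window.
* **Phenology (3)** — threshold = median of the 16-window EVI series; SOS is
  the first window strictly above it, EOS the last, LOS = EOS − SOS.
  "Strictly above" follows the literal threshold-exceedance rule; on series
  where nothing exceeds the median (flat or plateau-topped, which occurs on
  short truncated grids) the single-pixel API raises, while the pipeline uses
  a documented plateau policy: SOS/EOS collapse onto the first/last window
  attaining the row maximum.  EVI values at SOS/EOS are computed and exposed
  but kept out of the canonical 94-feature block (`include_pheno_evi=True`
  adds them).
* **Harmonic pair (2)** — least-squares fit of
  a₀ + Σₖ₌₁ⁿ [aₖ cos(2πkωt) + bₖ sin(2πkωt)] with ω = 1.5 and t = DOY/365
  (365 for all years).  The fit order is n = 2 — enough to absorb asymmetry
  while the stored features are only the k = 1 phase (atan2(b₁, a₁)) and
  amplitude (√(a₁²+b₁²)), matching a feature inventory that stores exactly
  one phase/amplitude pair.  Rounds with fewer than 5 windows (under-
  determined at n = 2) omit the pair and note it in the round manifest.
* **Accumulated EVI (1)** — the plain sum of composite EVI over windows in
  [SOS, EOS] inclusive (no trapezoid weighting), a biomass proxy.

## SAR features (40 per pixel)

σ⁰_VV and σ⁰_VH composites stay in dB for the statistical descriptors
(standard practice for backscatter statistics); CPR and RVI are computed on
linear power — products and sums of dB values are physically meaningless —
and summarised on that scale.  Seven statistics (adding the mean to the
optical six) × 4 parameters give 28 features.  A per-parameter *temporal*
PCA — centre-only standardisation (all windows share units), eigen-
decomposition of the across-window sample covariance, top three components —
contributes 12 score features.  The PCA is fitted on training samples only
and applied to all samples, so no validation information leaks into the
transform; eigenvector signs are fixed by making each component's largest-
magnitude loading positive, so scores are reproducible across runs.  Reading
the "3 components × 4 parameters" layout as one decomposition per parameter
(rather than a joint 64-dimensional PCA) is a deliberate choice.  In sweep
rounds with fewer than 4 windows the component count drops to
(windows − 1), recorded in the manifest.

## Refined Lee filter

Speckle is multiplicative gamma noise; the filter is the MMSE estimator
x̂ = m + k(y − m) with k = var_x/var_y and
var_x = (var_y − Cu²m²)/(1+Cu²), Cu² = 1/looks.  The refined variant
estimates the dominant gradient orientation from 3×3 sub-block means of the
7×7 window and takes local statistics from the edge-aligned half-plane on the
pixel's own side, preserving field boundaries.  Directed windows are used
only where the strongest block-mean gradient is significant against speckle
(default threshold: 3 standard deviations of a block-mean difference,
σ ≈ |m|·√(2Cu²/9)); on homogeneous texture the full square window is used
instead, because direction selection on pure speckle correlates with the
skewed local mean and would bias the output low.  A constant image passes
through unchanged; `refined=False` gives the plain square-window Lee filter.
The `looks` argument is the equivalent number of looks of the *input*: a
noise-free raster corresponds to a very large value.

## Classification and evaluation

The forest uses 100 trees and a minimum leaf population of 10; every other
hyperparameter stays at scikit-learn defaults and is recorded in run
manifests.  The 8:2 split is stratified per class; the per-class training
count is round-half-up of 0.8 n (giving 497/470/172 for 621/588/215), drawn
once per run and shared by all sources and all sweep rounds, so every round
scores the same validation ids.  Feature ranking is normalised MDI with
lexicographic tie-breaking.

Metrics follow the standard conventions: OA = trace/n; producer's accuracy =
correct/reference-total (omission side); user's accuracy = correct/predicted-
total (commission side); F1 = harmonic mean of the two; Cohen's Kappa from
the marginals.  A `swap_pa_ua` flag exposes the non-standard variant that
divides the other way.  Area accuracy = 1 − |A_gt − A_rs|/A_gt, returned
unclamped (negative when the mapped area more than doubles the reference).
The EIT uses a strict inequality (F1 > 0.9) on round-end DOYs.

## The synthetic scene generator

Each crop × band curve is a baseline plus logistic "bells"
(amplitude · expit(k_r(t−t_rise)) · expit(−k_f(t−t_fall))) — the standard
double-logistic phenology family.  Defaults were designed once to reproduce
the qualitative orderings that drive the method, and are the study
conditions for all tests:

* all crops: bell-shaped RE/NIR/EVI cycle, green-up ≈ DOY 170 (rice 185);
* rice: additive flood depression on SWIR1/SWIR2 (−0.08/−0.06 reflectance)
  and VV/VH (−5/−6 dB) inside DOY 120–200, keeping LSWI high and backscatter
  low season-long;
* soybean vs maize: identical until a divergence component switching on at
  DOY ≈ 200 — VH +3.0 dB and VV +1.5 dB for soybean against +0.7/+0.4 dB for
  maize (30% relative per-sample amplitude jitter, so the contrast does not
  average out to perfect separability), and a milder optical contrast
  (soybean SWIR1/SWIR2 +0.022/+0.018, maize RE2 −0.018, 15% jitter);
  soybean senesces at DOY ≈ 250 vs maize ≈ 262.

Observation noise: additive Gaussian reflectance noise (σ = 0.01 per band),
multiplicative gamma speckle applied in linear power (12 looks by default,
≈ 1.25 dB), per-sample sowing-date shifts (σ = 3 days, shared between
sensors) and 5% per-band amplitude jitter.  Sampling follows a 5-day optical
and 12-day SAR revisit over DOY 121–281; optical observations are cloud-
flagged independently with probability 0.3; default counts are 621 soybean /
588 maize / 215 rice.  Setting `amp_jitter_sd = 0` disables all amplitude
variability (including the divergence jitter) so fully deterministic scenes
can be generated; equal seeds give byte-identical scenes.

What the generator does **not** emulate: radiative-transfer realism, mixed
pixels and intercropping geometry, topographic and incidence-angle effects,
spatial correlation between neighbouring samples, multi-orbit same-day
duplicates, and real cloud spatial structure (flags are independent per
observation).  Passing tests therefore demonstrate that the pipeline
recovers the class structure it is designed for under controlled conditions,
not that the reported real-scene accuracies transfer.

## Problem sizes and runtime

The test suite and the acceptance script run the full-size scene (1,424
samples) for full-season classification (10 seeds) and for the 14-round
temporal sweep (10 seeds); a sweep takes ~15 s on one CPU, the whole
acceptance script a few minutes.  Example scripts use reduced scenes where
full size adds nothing.

## Known limitations

* Phenology on truncated early-season series is dominated by the plateau
  policy; SOS/EOS are only meaningful once the green-up is inside the span.
* The refined Lee filter's edge detector trades a small loss of sensitivity
  to faint edges for an unbiased mean on homogeneous speckle; faint-edge
  behaviour is tunable via `edge_factor`.
* Scene serialization is plain CSV and carries no geospatial metadata;
  georeferenced raster I/O is out of scope in this environment.
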