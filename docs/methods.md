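# Methods

This note documents the models, parameter choices and numerical
conventions behind `coastrisk`, and what the synthetic study regions
do and do not establish about real-data behavior.

## Flood model

The per-gauge flood climatology is a Poisson–GPD return curve:
threshold exceedances (height above μ, in m above MHHW) arrive as a
Poisson process at rate λ/yr with GPD-distributed magnitudes (scale σ,
shape ξ). The expected annual count of floods exceeding height z is
N₀(z) = λ[1 + ξ(z − μ)/σ]^(−1/ξ) for z ≥ μ, with three conventions:

* **ξ ≈ 0** — the exponential-tail limit λ·exp(−(z−μ)/σ) is used when
  |ξ| < 1e−8 (the general form is numerically unstable there).
* **ξ < 0** — the curve is identically zero beyond the finite upper
  endpoint μ − σ/ξ.
* **Sub-threshold extension** — between 0 m and μ the curve
  interpolates log-linearly from (μ, λ) down to (0 m, `cap_rate`),
  and is constant `cap_rate` below 0 m. The default cap of 182.6
  events/yr is the order of magnitude of daily high tides: land at or
  below the MHHW datum is flooded essentially every high tide, and
  p = 1 − exp(−182.6) is indistinguishable from 1. Results are
  insensitive to the cap's exact value for any site whose elevation is
  meaningfully above 0 m.

Sea-level rise enters by freeboard reduction: N_e(z) = E_s[N₀(z − s)],
estimated as the sample mean over the *full* SLR sample array (no
subsampling, no parametric refit), which keeps the engine agnostic to
the shape of the projection distribution. The annual probability of at
least one flood is p = 1 − exp(−N_e); the identity p ≤ N_e and the
consistency p = 1 − exp(−N_e) are enforced to 1e−12. The test suite
checks the sample-mean integration against adaptive quadrature of
∫N₀(z−s)f(s)ds for a smooth density (agreement <1% relative at 10⁵
samples); the check deliberately uses a compactly supported density
away from the sub-threshold cap, because rare excursions into the
~180/yr cap region dominate the Monte-Carlo variance and measure
sampling noise, not integration error.

**At-risk boundary.** Classification is p ≥ 0.01, inclusive. A
canonical 1-in-100-year event has N_e = 0.01 and hence
p = 1 − e^(−0.01) = 0.00995, marginally *below* 0.01: with a strict
inequality on p the defining example would be excluded. The threshold
is exposed as a parameter, and the expected count N_e is reported
alongside p so users can classify on either scale.

## Site ingest

* **Filtering** drops records with locational accuracy worse than
  50 m or zip-code-level geocoding, remediated/closed facilities, and
  records with regulatory end dates ≤ 2020; inactive facilities and
  expired permits are retained (residual hazards persist).
* **Categorization** uses a priority-ordered rulebook over program
  codes, industry codes and keywords; exactly one of eleven categories
  per record, records matching nothing are excluded and counted, and
  equal-priority conflicts are a configuration error rather than a
  silent tie-break.
* **Deduplication** collapses records agreeing on (category, exact
  coordinates) whose addresses are fuzzy-similar. Similarity is
  normalized indel similarity (2·LCS/(len a + len b)) on upper-cased,
  punctuation-stripped, whitespace-collapsed strings, threshold 0.8,
  computed by a direct LCS dynamic program (addresses are short
  strings; no dependency needed). Same-coordinate records in
  *different* categories are distinct facilities and kept. Same
  coordinates + same category + dissimilar addresses indicate a
  geocoding failure: they are flagged, and an injectable plausibility
  predicate decides retention (the default drops them).
* **Footprints**: point-in-parcel takes the parcel; otherwise a
  circular buffer whose area is the category's median
  intersected-parcel area (r = √(A_med/π)); oil/gas wells stay points
  (well pads are small). Legacy-defense-site (FUDS) geometries mix
  points and polygons: polygons are primary, outside points get
  buffers with the median *polygon* area clipped by any overlapping
  polygon, two-polygon overlaps are split evenly when the overlap is
  ≤45% of the smaller polygon and merged above that, and components of
  ≥3 mutually overlapping polygons are flagged unresolved rather than
  guessed at. An "even split" underdetermines the geometry; the
  overlap is divided along the perpendicular bisector of the two
  polygon centroids — the unique symmetric choice that assigns each
  overlap point to its nearer facility.
  Area is conserved under splits and the resolved set has zero
  pairwise overlap (asserted to 1e−9 in tests).
* **Elevation** is the 25th percentile (linear interpolation between
  order statistics) of DEM cell-center values inside the footprint;
  point sites read their containing cell. Each site is assigned the
  Euclidean-nearest tide gauge by footprint centroid — with synthetic
  gauges a few kilometers apart any distance-based rule gives the same
  assignment, and nearest-gauge is the standard convention.

## Exposure

Counties need ≥1 at-risk site under RCP 8.5/2100 to enter the study;
block groups must intersect the 3-km Euclidean buffer of the 10-m
elevation line, computed as the polygonized boundary of sub-10-m land
cells. Populated cells are 30-m grid cells with population > 0 whose
*centers* fall inside the block group (boundary-straddling cells with
outside centers are excluded); with no population raster the whole
polygon is treated as populated (fallback mode, recorded in the run
manifest). Distance runs from populated cell centers to the *nearest
point of the site footprint* — footprints exist precisely to represent
a site's extent, so edge distance, not centroid distance, decides
proximity. A site counts once per block group. EAE sums p over at-risk
sites only; since every at-risk site has p ≥ 0.01, the invariant
0.01·n_sites ≤ EAE ≤ n_sites holds for every record and is tested.

## Equity statistics

Continuous covariates are z-scored with the mean/SD of the full
coastal universe (not only exposed block groups); the binary
disadvantaged-community flag stays on {0,1}. One covariate per model.
The logistic model (exposed flag) drops counties with no outcome
variation — their fixed effect is not identified — with a logged
count; the negative-binomial model is NB2 with ML dispersion; the
linear model targets EAE. All three include population density and
county indicator variables, and report county-clustered sandwich
standard errors with the usual finite-cluster correction
G/(G−1)·(N−1)/(N−k). 95% CIs use ±1.96·SE on the estimation (log for
OR/IRR) scale. A zero-variance density column is omitted from the
design rather than left to make it singular.

Concentration curves sort block groups by descending covariate (ties
broken by stable input order), cumulate equal block-group shares on x
and burden shares on y, and C = 1 − 2·(trapezoid area). Equal
weighting of block groups matches the curve's x-axis definition
(cumulative share of block groups); population weighting is a
straightforward extension but not the default. The bootstrap CI
resamples block groups with replacement (percentile 2.5/97.5,
deterministic per seed, ≥100 replicates enforced); all-zero resamples
are redrawn since the curve is undefined without burden.

## Synthetic regions

The generator builds planar regions in meters (no geographic CRS, so
Euclidean distances are exact): a wavy coastline at 0 m, elevation
ramping linearly to ~28 m at the inland edge with spatially correlated
Gaussian noise (σ = 0.6 m, correlation length ~6 cells), counties in a
coastal and an inland tier (the inland tier sits above the 18-m line,
so study-area restriction has something to exclude), block groups as
vertical strips clipped to land, and three tide gauges with λ ∈ [2,5],
μ ∈ [0.5,1], σ ∈ [0.1,0.25], ξ ∈ [−0.1,0.15]. SLR distributions are
sample arrays: a scenario/year median (0.24/0.55 m for RCP 4.5 at
2050/2100; 0.29/0.90 m for RCP 8.5 — central values of the order
published localized projections give for U.S. gauges) plus a small
per-gauge vertical-land-movement offset and a median-centered
lognormal deviation; a `slr_spread=0` switch produces degenerate
(single-atom) distributions for exact-truth tests. Site density decays
inland (exponential, scale 22% of the region width); near-duplicates
(8% by default) perturb addresses by abbreviation/casing/typo
operators; offshore wells are placed seaward of all block groups.

The marginalization covariate is generated *conditional on* true
exposure: county intercepts are solved (Gauss–Hermite quadrature +
root finding) so that a logistic model with the configured
standardized slope reproduces each county's exposure rate, then the
covariate is drawn from the Bayes conditional by rejection sampling.
This makes the regression's data-generating process hold exactly, so
parameter-recovery tests are testing the estimator, not a hoped-for
approximation. The covariate is expressed as a proportion via a
linear map (0.3 + 0.1·z, clipped to [0,1]; clipping mass < 1e−3), so
downstream universe z-scoring recovers the generative slope without
link distortion. Generative truth — at-risk sets per scenario-year
(computed with generator-side closed forms, independent of the flood
module), SLR medians, the association slope, county intercepts, and
the true exposed block-group set — is recorded on the region for
recovery tests.

A lightweight tabular generator (`simulate_exposure_covariates`)
forward-simulates the same exposure/covariate/county structure without
geometry; the parameter-recovery studies (100 replicates at n = 4000
block groups, 25 counties) use it so they run in seconds.

**What the synthetic regions do not emulate:** real geomorphology,
tides or storm physics; spatial autocorrelation of demographics beyond
county structure; registry schemas; geocoding error structure beyond
the injected perturbations; the national scale (the worked example
runs ~150 records over 24 × 16 km — percentages of at-risk sites are
therefore much higher than a national analysis would produce, by
construction of a compact coastal region). Passing tests establish
that the pipeline's operations implement their definitions and that
the estimators recover known truth under the stated generative model —
not that real-data results would match any particular published
number.

## Problem sizes and determinism

Test regions use a 60-m cell on a 12 × 8 km extent (~27k cells, 40
block groups); the worked example uses 60 m on 24 × 16 km. Every
generator is a pure function of (config, seed); pipelines rerun
byte-identically, and bootstrap/bootstrap-like procedures take
explicit seeds. Rasters serialize as Esri ASCII grid text (exact
enough at %.6f for meter-scale elevations), vectors as GeoJSON with a
planar-meters CRS tag, tables as CSV with round-trip float precision.

## Known limitations

* Flood frequency and magnitude are static over the century: no storm
  intensification, groundwater intrusion, attenuation over wide flats,
  or marsh loss. The model is a freeboard ("modified bathtub")
  amplification of today's return curve.
* The sub-threshold return-curve extension is a convention; only sites
  with elevations near or below the gauge threshold are sensitive to
  it.
* Three-or-more-way FUDS overlaps are flagged, not resolved (real
  analyses resolve these by hand).
* The concentration-index bootstrap treats block groups as
  exchangeable; spatial dependence beyond counties is ignored, as in
  the regression clustering.
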