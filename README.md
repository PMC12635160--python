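# coastrisk

Coastal flood-risk and exposure-equity analysis for hazardous sites
under probabilistic sea-level rise (SLR).

Sea-level rise amplifies the frequency of coastal floods, and many of
the facilities that store, process, or emit hazardous substances —
refineries, ports and terminals, sewage treatment plants, industrial
facilities, oil and gas wells, legacy defense sites — sit on low-lying
coastal land. `coastrisk` is a pipeline for asking two questions about
such a region: *which sites face a meaningful annual chance of
flooding under a given emissions scenario and horizon year*, and
*whether the neighborhoods living next to those at-risk sites are more
socially marginalized than the neighborhoods that are spared*. It is
aimed at environmental-health and environmental-justice researchers
who want a tested, reproducible implementation of this kind of
hazard-equity analysis, exercised end-to-end on synthetic coastal
regions with known generative truth.

## The model

**Flood hazard.** A tide gauge's flood climatology is a
Poisson–generalized-Pareto (GPD) return curve. Floods exceeding the
gauge threshold μ (m above mean higher high water, MHHW) arrive at
rate λ per year and the expected number of floods per year exceeding
height *z* is

    N₀(z) = λ [1 + ξ (z − μ)/σ]^(−1/ξ),      z ≥ μ

(exponential-tail limit as ξ→0, zero beyond the finite endpoint when
ξ<0; below the threshold the curve is extended log-linearly to a
capped daily-tide rate at 0 m). Local sea-level rise *s* lowers a
site's effective freeboard, and integrating over a probabilistic SLR
projection — an array of samples per gauge × scenario (RCP 4.5 / 8.5)
× year (2050 / 2100) — by the law of total probability gives

    N_e(z) = E_s[N₀(z − s)],     p = 1 − exp(−N_e).

A site is **at risk** when p ≥ 0.01 (the 1-in-100-year criterion). The
site elevation *z* is the 25th percentile of ground elevation over the
site's footprint — a tax parcel, a median-area buffer, or a resolved
legacy-defense-site polygon — because flooding is controlled by a
site's low ground.

**Exposure.** Counties with at least one at-risk site (RCP 8.5, 2100)
define the study area; block groups within 3 km of the 10-m elevation
line form the coastal universe. A block group is *exposed* when a
populated 30-m grid cell of it lies within 1 km (3 km in sensitivity
analyses) of an at-risk site's footprint. Its **expected annual
exposure (EAE)** is the sum of annual flood probabilities over those
sites — the expected number of nearby sites flooded in a year.

**Equity.** Each marginalization covariate (one at a time, z-scored
against the coastal universe) enters a logistic model of the exposed
flag with population density and county fixed effects,
county-clustered robust standard errors, and is reported as an odds
ratio per SD; negative-binomial (site count) and linear (EAE) models
run among exposed block groups. Concentration curves order block
groups by descending marginalization and cumulate burden shares; the
concentration index C = 1 − 2·(area under the curve) is negative when
the burden concentrates among more marginalized neighborhoods, with a
nonparametric bootstrap CI.

## Worked example

```bash
cd analysis
python 01_generate_region.py   # synthetic region + fixture bundle
python 02_ingest_sites.py      # registry cleaning
python 03_flood_risk.py        # per-site annual flood probabilities
python 04_exposure.py          # coastal universe + block-group outcomes
python 05_equity.py            # disparity statistics
python 06_report.py            # summary arithmetic
```

On the default study region (seed 7, 24 × 16 km, six counties, ~150
raw site records), the ingest stage reports

```
"n_raw": 149, "n_dropped_filter": 37, "n_after_dedupe": 104,
"n_offshore_wells_excluded": 4, "n_final_sites": 100
```

— 37 records are dropped for imprecise coordinates, remediation or
regulatory end dates, near-duplicates collapse 104→100 with offshore
wells removed. The flood stage then finds 32 of 100 sites at risk
under RCP 8.5 by 2100 versus 29 under RCP 4.5:

```
limiting emissions to RCP4.5 reduces 2100 at-risk sites 32 -> 29
(reduction of 3, 9% of sites)
```

and the equity stage recovers the generative association planted by
the synthetic-data module (a true standardized odds ratio of 1.40
linking the poverty share to exposure):

```
generative covariate pct_poverty: true standardized OR 1.40,
estimated 1.61 [0.97, 2.68]
pct_poverty  concentration index -0.278 [-0.488, -0.025]  significant
```

The point estimate sits inside its CI around the truth (one small
region; the dedicated recovery study in the test suite runs 100
replicates at n = 4000 block groups and centers on 1.40), and the
negative, significant concentration index says at-risk site burden
concentrates in higher-poverty block groups — exactly the structure
the generator planted.

A `coastrisk` CLI wraps the same stages (`coastrisk synth`,
`coastrisk run --config cfg.yaml --out dir/`, plus per-stage
subcommands); see `coastrisk --help`.

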