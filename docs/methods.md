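# Methods

This note documents the models and numerical choices behind `diarrscan`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Data model

The unit of analysis is a complete rectangular panel of nonnegative
integer counts indexed by (reporting unit, month), with months stored as
0-based consecutive integers from panel start; calendar labels are
metadata. Completeness is enforced at read time — a missing (unit, month)
cell raises an error naming the cell rather than being zero-filled,
because a silent zero is indistinguishable from a reporting gap and would
bias every downstream expectation. Each unit carries one representative
point coordinate (decimal degrees; WGS84 is assumed since the source data
state no datum) and an under-five base population at panel start.

## Population projection and person-time

Denominators follow compound growth `P(t) = P₀(1+r)^t` with `t` in years;
the monthly panel uses the fractional exponent `t = m/12`, which agrees
with the annual formula at every 12-month boundary and grows smoothly in
between. Defaults: `r = 0.029`/yr (the regional growth rate of the
emulated zone) and an under-five fraction of 0.156 when projecting from a
total census population. Person-time is treated as exact (no census
uncertainty); all rate and expectation formulas are invariant to a global
rescaling of person-time, which the tests assert.

## Expected counts and excess risk

Null expectations are proportional allocation, `E[c] = p·C/P` per cell,
which conserves the total (ΣE = C) by construction. Per-unit excess risk
is the standardized morbidity ratio `c/E` (the field calls this SMR even
for morbidity outcomes); the relative risk uses the outside-window
baseline, `RR = (c/E)/((C−c)/(C−E))`. The two columns are kept distinct
because they answer different questions (rate vs the rest of the map vs
rate vs the whole map), and |RR−1| ≥ |SMR−1| always, with equality only as
the unit's share of expectation vanishes.

## Seasonal-trend decomposition

The decomposition is the classical multiplicative ratio-to-moving-average:

1. 12-term moving average, centered by averaging two adjacent placements
   (equivalently a 13-term filter with weights 1/24, 10 × 1/12, 1/24).
   The CMA is exact for affine series at interior points and annihilates
   any zero-mean 12-month-periodic component; both are tested properties.
   The first and last 6 months have no centered value and are excluded
   from index estimation rather than padded.
2. Seasonal indices: calendar-month means of series/CMA, renormalized to
   mean exactly 1 (so deseasonalize-then-reseasonalize is the identity).
3. Trend: ordinary least squares of the deseasonalized series on the
   1-based month index. The intercept therefore refers to the month-0
   extrapolation; this origin convention is stated here because the
   emulated study's published trend line does not state its own.

A multiplicative model (not additive) is used because surveillance counts
scale with population and season; the implementation rejects nonpositive
values rather than silently switching models. Series must span ≥ 24
months so every calendar month appears in the CMA-covered interior.

## Scan statistic

Discrete-Poisson Kulldorff scan. Window families:

* **Spatial**: for each unit as center, circles grown one distance ring
  at a time (units at exactly tied distances enter together, so a circle
  always contains *every* unit within its radius), stopping before the
  circle exceeds 50% of total person-time (configurable in (0, 0.5]).
  Duplicate member sets from different centers are kept once. Distance is
  Euclidean on raw decimal degrees by default — matching the emulated
  study's stated use of plain Cartesian coordinates at zonal scale —
  with great-circle (haversine) available by config.
* **Temporal**: all month intervals up to ⌊0.5·n_months⌋ long, at 1-month
  aggregation.
* **Space-time**: every admissible circle × every admissible interval;
  the spatial cap applies to the base's full-period person-time (the
  SaTScan convention), the temporal cap to the interval length.

Scoring is the Poisson window log-likelihood ratio
`c·ln(c/E) + (C−c)·ln((C−c)/(C−E))` with the high-rates indicator
(windows with `c ≤ E` score 0); boundary terms follow `x·ln x → 0`. The
implementation evaluates all windows through shared circle bases and
month cumulative sums, and the test suite proves it equivalent to a
from-first-principles enumerator on small panels (the two code paths
share nothing: distance-threshold circles vs nearest-neighbour growth,
per-cell loops vs matrix cumsums).

Inference conditions on the observed total: each Monte Carlo replicate
redistributes the C cases multinomially over cells with probabilities
E/C, the replicate is rescanned over the same window family, and
`p = (1 + #{replicate maxima ≥ LLR}) / (1 + R)`, so the smallest
attainable p with R = 999 is 0.001 (0.005 with R = 199). Reporting is
greedy in LLR order: a cluster is reported only if significant (default
α = 0.05) and sharing no unit (spatial/space-time) or no month (temporal)
with anything already reported. Ties in LLR break toward the smaller
window, then lexicographically, so output order is deterministic.

Parameter defaults (all in `ScanConfig`): 50% spatial population cap, 50%
temporal cap, 1-month aggregation, 999 replicates, high rates only.

## Synthetic data generator

Cell counts are independent Poisson draws with intensity

```
λ(u, m) = person_time(u, m) · base_rate · s(month(m)) · (1+g)^m · rr(u, m)
```

where `s` is a 12-index multiplicative seasonal pattern (mean 1; default
peaks February–May at 1.20–1.35 and troughs July–December at 0.80,
starting from a July fiscal year), `g` a multiplicative monthly trend
(default 0.003/month), and `rr(u, m)` the planted-cluster multiplier. A
cell inside several planted windows takes the multiplier of the *first*
window that covers it — multipliers do not stack — so each planted
window's alternative hypothesis is exactly the scan's (a constant risk
ratio inside the window). A negative-binomial option (gamma-mixed
Poisson) exists for robustness experiments and is off by default, because
the scan's own model assumes Poisson.

`sidama_scenario()` emulates the Sidama Zone study: 19 districts over 72
months, base rate 5,822 per 100,000 per year, expected panel total
calibrated to 202,406 cases (times an optional `population_scale`).
Geography uses the ten published district coordinates plus nine
deterministic synthetic placements inside the zone's bounding box;
relative populations are the districts' published shares of the
null-expected caseload. Three clusters are planted: Boricha × all months,
a Malga × months 17–46 cylinder, and a zone-wide months 29–46 temporal
cluster. Their multipliers are *calibrated by fixed point* so each
window's emergent observed/expected and relative risk — computed from the
expected panel exactly as the scan computes them, renormalization
included — equal the published pairs (1.70/1.82, 2.00/2.03, 1.26/1.37).
Planting the published RRs directly as raw multipliers would understate
every emergent effect (the planted excess inflates the panel total that
expectations are normalized to) and misstate the competitive structure
among windows; with the calibration, the scenario also reproduces the
published LLR magnitudes (the cylinder scores ≈1,200 at full scale
against a published 1,214.67).

What the generator does **not** emulate: reporting artifacts (under-
reporting, facility-opening trends), overdispersion beyond Poisson (off
by default), spatially heterogeneous diffuse excess (the temporal cluster
is a uniform blanket), climate-driven intensity, or real district
polygons. Passing recovery tests therefore demonstrate that the scan
finds constant-risk-ratio windows planted under its own model in
study-like geometry — not that every real-data cluster would be found.

## Problem sizes in the test suite

Simulation-based tests run at reduced sizes chosen to keep the suite
quick while preserving the statistical point: oracle equivalence uses
5 × 12 panels (small enough for exhaustive enumeration); recovery runs
the full 19 × 72 geometry at 1/10 population scale with 199 replicates
over 20 seeds; type-I error uses 100 null panels with 199 replicates.
Under the null the Monte Carlo p-value is discrete and conservative, so
the observed rejection rate at α = 0.05 is expected at or below 5%
(binomial tolerance applied).

## Known limitations

* Circular windows only; elliptic windows and the space-time permutation
  model are out of scope, as are covariate adjustment and prospective
  surveillance.
* The degree-space distance metric distorts east-west distances by
  cos(latitude) ≈ 0.7% at 6–7°N — negligible at zonal scale, and
  consistent with the emulated study; use `great_circle` elsewhere.
* Monte Carlo p-values inherit the 1/(R+1) floor; ranking among clusters
  far above the null is by LLR, not p.
* The per-unit excess-risk map is unsmoothed (no empirical-Bayes or BYM
  shrinkage); small units with small expectations fluctuate accordingly.
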