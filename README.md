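# diarrscan

Space-time cluster detection and seasonal-trend analysis for district-month
disease count panels, built around the discrete-Poisson Kulldorff scan
statistic. The package grew out of zonal under-five diarrhea surveillance in
Southern Ethiopia (19 districts reporting monthly counts over six fiscal
years, July–June), but every component works on any rectangular
(unit × month) count panel with point locations and population denominators.

It is aimed at epidemiologists and surveillance analysts who want the full
SaTScan-style workflow — population projection, incidence rates,
seasonal decomposition, excess-risk (SMR) mapping, and purely spatial /
purely temporal / space-time cluster detection with Monte Carlo inference —
as a scriptable, testable Python library instead of a GUI.

## The statistics

**Null expectations.** Under spatial-temporal randomness the expected count
in any cell is proportional to its person-time: `E[c] = p·C/P`, with `p` the
cell's person-time and `C`, `P` the panel totals. Person-time comes from
compound-growth projection `P(t) = P₀(1+r)^t` (monthly exponent `m/12`),
optionally thinned to the under-five band by a fixed fraction.

**Scan statistic.** Candidate clusters are circles of nearest-neighbour
units (capped at 50% of the population at risk), month intervals (capped at
50% of the study period), or cylinders combining both. Each window is
scored with the Poisson window log-likelihood ratio

```
LLR = c·ln(c/E) + (C−c)·ln((C−c)/(C−E))   if c > E, else 0
```

and the window relative risk is `RR = (c/E) / ((C−c)/(C−E))`. Significance
comes from Monte Carlo replication: the `C` observed cases are redistributed
multinomially with cell probabilities `E/C`, each replicate is rescanned,
and `p = (1 + #{replicate maxima ≥ LLR}) / (1 + R)`. Secondary clusters are
reported greedily in LLR order subject to no shared units (or months, for
temporal scans).

**Seasonality.** Monthly rates are smoothed with the 12-term centered
moving average (weights 1/24, 10×1/12, 1/24), seasonal indices are
calendar-month means of the ratio-to-CMA renormalized to mean 1, and the
trend is the OLS line through the deseasonalized series.

A synthetic-data module generates Poisson count panels with multiplicative
seasonality, growth trend, and planted clusters of known relative risk —
including a ready-made 19-district scenario calibrated so the planted
clusters' emergent observed/expected ratios and relative risks match the
published Sidama Zone values (1.70/1.82 spatial, 2.00/2.03 space-time,
1.26/1.37 temporal).

## Worked example

```python
import diarrscan as d

# a study-like synthetic panel at 1/10 population scale
cfg = d.sidama_scenario(seed=0, population_scale=0.1)
cases, pop, locations, truth = d.generate_panel(cfg)

sc = d.ScanConfig(n_replicates=199, seed=42)
windows = d.enumerate_spacetime_windows(locations, pop, cases.n_months, sc)
reported = d.report_clusters(d.scan(cases, pop, windows, sc))
for r in reported[:2]:
    print(r.rank, r.window.member_units, r.window.month_range,
          r.observed, round(r.expected, 1), round(r.relative_risk, 2),
          round(r.llr, 1), r.p_value)
```

prints

```
1 ('boricha',) (39, 71) 1587 825.2 2.0 291.2 0.005
2 ('malga',) (17, 46) 615 311.2 2.01 117.5 0.005
```

Rank 1 is a space-time projection of the planted all-period spatial
cluster (the scan finds its hottest admissible sub-cylinder, here the last
33 months, where the seasonal peak and growth trend compound); rank 2
recovers the planted 30-month cylinder exactly — months 17–46 with a
relative risk of 2.01 against a target of 2.03 — at the smallest attainable
p-value with 199 replicates, 1/200 = 0.005.

The same pipeline runs from the shell:

```bash
diarrscan simulate --out-dir sim --seed 0 --population-scale 0.1
diarrscan scan --cases-csv sim/cases.csv --locations-csv sim/locations.csv \
    --mode spacetime --replicates 199 --seed 42 --out-prefix clusters
diarrscan run --config pipeline.json   # full analysis, all artifacts
```

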