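"""Published district-level summary statistics for the Sidama Zone study.

The six-year (July 2011 – June 2017) HMIS under-five diarrhea panel behind
these numbers was never deposited, but the study's summary tables were:
yearly incidence rates per district, district observed/expected counts with
excess risk and relative risk, and the detected spatial / temporal /
space-time clusters with their likelihood statistics.  They are shipped
here as in-memory tables so the package's own formulas can be validated
against the printed values.

Spelling is canonicalized: the source prints both "Wensho" and "Wonsho"
for the same district; "Wonsho" is used throughout.  The source also
prints the Malga spatial-cluster RR as 1.65 while the identical
(observed, expected) pair elsewhere yields — and is elsewhere printed
as — 1.63; both printed values are stored as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Grand total of reported under-five diarrhea cases over the 72 months.
TOTAL_CASES: int = 202_406

#: Zone-wide annual incidence, cases per 100,000 under-five population.
ANNUAL_RATE_PER_100K: float = 5822.0

#: Regional annual population growth rate used for projection.
ANNUAL_GROWTH_RATE: float = 0.029

#: Under-five share of the total projected population.
UNDERFIVE_FRACTION: float = 0.156

#: Fitted deseasonalized trend, rate per 1000 per month: Y(t) = slope*t + intercept.
TREND_SLOPE: float = 0.015
TREND_INTERCEPT: float = 4.27

_YEARS = ["2011/12", "2012/13", "2013/14", "2014/15", "2015/16", "2016/17"]

# Yearly incidence rate per 1000 under-five population, by district.
_TABLE1 = [
    ("Aleta Chuko", 56.0, 44.9, 57.9, 56.6, 61.2, 54.7),
    ("Aleta Wondo", 56.0, 64.0, 84.7, 95.4, 60.2, 70.6),
    ("Arbegona", 52.4, 42.5, 63.9, 68.3, 43.9, 52.0),
    ("Aroresa", 31.6, 35.5, 43.8, 27.7, 22.4, 31.2),
    ("Bensa", 24.5, 18.3, 26.1, 27.9, 17.5, 17.3),
    ("Bona", 26.1, 49.1, 51.2, 48.1, 40.2, 65.2),
    ("Boricha", 88.3, 62.0, 85.1, 121.8, 95.7, 135.8),
    ("Bursa", 50.7, 31.4, 33.9, 26.7, 24.2, 17.5),
    ("Chirie", 18.6, 91.3, 82.7, 37.4, 17.3, 27.2),
    ("Dale", 115.2, 38.5, 50.7, 59.6, 53.4, 58.1),
    ("Dara", 59.7, 48.0, 53.0, 64.2, 52.8, 44.4),
    ("Gorchie", 45.9, 42.0, 65.8, 63.8, 46.3, 32.1),
    ("Hawassa Zuria", 40.2, 37.8, 30.3, 59.8, 41.2, 51.3),
    ("Hulla", 35.9, 39.9, 94.4, 129.2, 111.1, 107.1),
    ("Loka Abaya", 94.7, 61.2, 55.8, 64.9, 40.3, 63.7),
    ("Malga", 71.4, 99.2, 115.7, 106.7, 76.3, 85.9),
    ("Shebedino", 55.3, 60.9, 77.3, 90.6, 62.6, 79.3),
    ("Wonsho", 44.2, 20.8, 55.6, 52.9, 50.1, 60.9),
    ("Wondogenet", 32.0, 40.9, 56.1, 63.8, 79.9, 75.8),
]

# District observed and expected cases with printed obs/exp and RR,
# ordered by descending excess risk as published.
_TABLE2 = [
    ("Boricha", 29_153, 17_146.87, 1.70, 1.82),
    ("Malga", 11_952, 7_522.60, 1.59, 1.63),
    ("Hulla", 13_335, 8_856.59, 1.51, 1.54),
    ("Aleta Wondo", 16_005, 12_947.92, 1.24, 1.26),
    ("Shebedino", 19_636, 16_027.43, 1.23, 1.25),
    ("Loka Abaya", 7_351, 6_799.06, 1.08, 1.08),
    ("Dale", 17_713, 16_626.00, 1.07, 1.07),
    ("Wondogenet", 10_792, 10_668.99, 1.01, 1.01),
    ("Aleta Chuko", 10_883, 11_462.75, 0.95, 0.95),
    ("Arbegona", 8_606, 9_308.74, 0.92, 0.92),
    ("Dara", 9_786, 10_638.18, 0.92, 0.92),
    ("Gorchie", 6_102, 7_226.53, 0.84, 0.84),
    ("Wonsho", 5_045, 6_143.31, 0.82, 0.82),
    ("Bona", 6_713, 8_306.62, 0.81, 0.80),
    ("Chirie", 6_407, 8_252.70, 0.78, 0.77),
    ("Hawassa Zuria", 6_391, 8_528.34, 0.75, 0.74),
    ("Aroresa", 6_393, 11_664.18, 0.55, 0.53),
    ("Bursa", 3_691, 7_100.39, 0.52, 0.51),
    ("Bensa", 6_452, 17_178.83, 0.38, 0.36),
]

# Spatial clusters: rank, district, population, lat, lon, observed, expected,
# annual cases/100k, obs/exp, RR (as printed), LLR.  All p < 0.001.
_TABLE3 = [
    (1, "Boricha", 49_076, 6.939005, 38.253064, 29_153, 17_146.87, 9898.2, 1.70, 1.82, 3864.33),
    (2, "Malga", 21_530, 6.933700, 38.562860, 11_952, 7_522.60, 9249.8, 1.59, 1.65, 1154.94),
    (3, "Hulla", 25_348, 6.487117, 38.522366, 13_335, 8_856.59, 8765.7, 1.51, 1.54, 1030.89),
    (4, "Shebedino", 45_872, 6.874400, 38.441810, 19_636, 16_027.43, 7132.6, 1.23, 1.25, 413.94),
    (5, "Aleta Wondo", 37_058, 6.596820, 38.422840, 16_005, 12_947.92, 7196.4, 1.24, 1.26, 360.24),
    (6, "Dale", 47_585, 6.745428, 38.409888, 17_713, 16_626.00, 6202.4, 1.07, 1.07, 37.97),
    (7, "Loka Abaya", 19_459, 6.694306, 38.202427, 7_351, 6_799.06, 6294.4, 1.08, 1.08, 22.60),
]

# Space-time clusters: rank, district, population, lat, lon, time frame,
# observed, expected, annual cases/100k, obs/exp, RR, LLR.  All p < 0.001.
_TABLE4 = [
    (1, "Malga", 21_530, 6.933700, 38.562860, "2012-12", "2015-05", 6_186, 3_097.21, 11_627.8, 2.00, 2.03, 1214.67),
    (2, "Loka Abaya", 19_459, 6.694306, 38.202427, "2012-01", "2012-05", 900, 441.07, 11_879.4, 2.04, 2.05, 183.47),
    (3, "Bursa", 20_322, 6.590160, 38.606330, "2011-12", "2011-12", 327, 93.27, 20_410.6, 3.51, 3.51, 176.61),
    (4, "Gorchie", 20_683, 6.876740, 38.584650, "2014-03", "2014-04", 479, 199.43, 13_983.0, 2.40, 2.41, 140.34),
    (5, "Wonsho", 17_583, 6.749010, 38.517450, "2012-03", "2012-03", 216, 81.28, 15_471.9, 2.66, 2.66, 76.44),
]

#: The single purely temporal cluster: all districts, Dec 2013 – May 2015.
TEMPORAL_CLUSTER = {
    "start": "2013-12",
    "end": "2015-05",
    "observed": 63_683,
    "expected": 50_695.23,
    "relative_risk": 1.37,
    "llr": 2109.93,
}


@dataclass(frozen=True)
class ReferenceTables:
    """Bundle of the published summary tables, as pandas DataFrames."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    temporal_cluster: dict = field(default_factory=lambda: dict(TEMPORAL_CLUSTER))
    total_cases: int = TOTAL_CASES
    annual_rate_per_100k: float = ANNUAL_RATE_PER_100K
    annual_growth_rate: float = ANNUAL_GROWTH_RATE
    underfive_fraction: float = UNDERFIVE_FRACTION
    trend_slope: float = TREND_SLOPE
    trend_intercept: float = TREND_INTERCEPT


def reference_tables() -> ReferenceTables:
    """Return the published Sidama Zone summary tables as DataFrames."""
    t1 = pd.DataFrame(_TABLE1, columns=["district", *_YEARS])
    t2 = pd.DataFrame(
        _TABLE2,
        columns=["district", "observed", "expected", "obs_over_exp", "relative_risk"],
    )
    t3 = pd.DataFrame(
        _TABLE3,
        columns=[
            "rank", "district", "population", "lat", "lon",
            "observed", "expected", "annual_per_100k",
            "obs_over_exp", "relative_risk", "llr",
        ],
    )
    t4 = pd.DataFrame(
        _TABLE4,
        columns=[
            "rank", "district", "population", "lat", "lon",
            "start", "end", "observed", "expected", "annual_per_100k",
            "obs_over_exp", "relative_risk", "llr",
        ],
    )
    return ReferenceTables(table1=t1, table2=t2, table3=t3, table4=t4)
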