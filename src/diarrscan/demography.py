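"""Population projection and incidence rates.

Denominators come from compound-growth projection of a census reference
population, P(t) = P0 * (1 + r)^t with t in years, thinned to the
under-five age band by a fixed fraction.  Monthly person-time uses the
fractional exponent t = m/12 so the panel grows smoothly and agrees with
the annual formula at every 12-month boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LocationTable, PopulationPanel


@dataclass(frozen=True)
class ProjectionConfig:
    """Compound-growth projection parameters.

    annual_growth_rate is a proportion per year (0.029 = 2.9%/yr);
    underfive_fraction is the under-five share of the total population.
    """

    annual_growth_rate: float = 0.029
    underfive_fraction: float = 0.156
    reference_year: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.underfive_fraction < 1:
            raise ValueError("underfive_fraction must be in (0, 1)")
        if self.annual_growth_rate <= -1:
            raise ValueError("annual_growth_rate must exceed -1")


def project_population(
    reference_population: float,
    config: ProjectionConfig,
    elapsed_years: float,
    underfive: bool = False,
) -> float:
    """P0 * (1+r)^t, optionally scaled to the under-five sub-population."""
    if elapsed_years < 0:
        raise ValueError("elapsed_years must be nonnegative")
    p = reference_population * (1.0 + config.annual_growth_rate) ** elapsed_years
    if underfive:
        p *= config.underfive_fraction
    return p


def monthly_population_panel(
    locations: LocationTable, config: ProjectionConfig, n_months: int
) -> PopulationPanel:
    """Person-time panel: base_population(unit) * (1+r)^(m/12) for month m.

    Base populations in the location table are taken as already being the
    under-five population at panel start; the under-five fraction applies
    only when projecting from a total census figure.
    """
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    m = np.arange(n_months, dtype=float)
    growth = (1.0 + config.annual_growth_rate) ** (m / 12.0)
    pt = locations.base_population[:, None] * growth[None, :]
    return PopulationPanel(locations.unit_ids, pt)


def incidence_rate(cases: float, person_time: float, per: float = 1000.0) -> float:
    """Cases per ``per`` persons of person-time."""
    if person_time <= 0:
        raise ValueError("person_time must be positive")
    return cases / person_time * per


def yearly_rate_table(cases, pop, per: float = 1000.0):
    """Per-unit yearly incidence rates (12-month blocks of the panel).

    Returns a DataFrame shaped like the study's yearly-rate table: one row
    per unit, one column per panel year.  Person-years are the mean monthly
    population over each block.
    """
    import pandas as pd

    n_years = cases.n_months // 12
    rows = {}
    for i, u in enumerate(cases.unit_ids):
        vals = []
        for y in range(n_years):
            sl = slice(12 * y, 12 * (y + 1))
            c = cases.counts[i, sl].sum()
            person_years = pop.person_time[i, sl].mean()
            vals.append(incidence_rate(c, person_years, per))
        rows[u] = vals
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"year_{y+1}" for y in range(n_years)]
    )
    df.index.name = "unit_id"
    return df
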