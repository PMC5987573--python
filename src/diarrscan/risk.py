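"""Expected counts under spatial randomness and per-unit excess risk.

Under the null hypothesis the expected count in any cell is proportional
to its person-time: E[c] = p * C / P, where p is the cell's person-time
and C, P the panel totals.  The per-unit ratio of observed to expected
cases is the excess risk (the standardized morbidity ratio, SMR); the
relative risk compares the unit's rate to the rate everywhere else,
RR = (c/E) / ((C-c)/(C-E)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CasePanel, PanelError, PopulationPanel


@dataclass(frozen=True)
class RiskRow:
    unit_id: str
    observed: int
    expected: float
    obs_over_exp: float  # excess risk / SMR
    relative_risk: float


def expected_counts(cases: CasePanel, pop: PopulationPanel) -> np.ndarray:
    """Null-expected counts per cell, E(unit, m) = p(unit, m) * C / P.

    The expected panel conserves the total: sum(E) == C up to float
    rounding.
    """
    if cases.unit_ids != pop.unit_ids or cases.counts.shape != pop.person_time.shape:
        raise PanelError("case and population panels must share the same index")
    C = cases.total_cases
    return pop.person_time * (C / pop.total)


def relative_risk(c: float, expected: float, total_cases: float) -> float:
    """(c/E) / ((C-c)/(C-E)) — rate inside vs outside the unit/window."""
    if total_cases - c <= 0:
        raise ValueError("relative risk undefined when the window holds all cases")
    if total_cases - expected <= 0:
        raise ValueError("relative risk undefined when E >= C")
    return (c / expected) / ((total_cases - c) / (total_cases - expected))


def excess_risk_table(cases: CasePanel, pop: PopulationPanel) -> list[RiskRow]:
    """Per-unit observed, expected, SMR and RR, sorted by SMR descending."""
    E = expected_counts(cases, pop)
    C = cases.total_cases
    rows = []
    for i, u in enumerate(cases.unit_ids):
        c = int(cases.counts[i].sum())
        e = float(E[i].sum())
        rows.append(
            RiskRow(
                unit_id=u,
                observed=c,
                expected=e,
                obs_over_exp=c / e,
                relative_risk=relative_risk(c, e, C),
            )
        )
    rows.sort(key=lambda r: r.obs_over_exp, reverse=True)
    return rows


def excess_risk_frame(cases: CasePanel, pop: PopulationPanel) -> pd.DataFrame:
    """DataFrame view of :func:`excess_risk_table` (one row per unit)."""
    rows = excess_risk_table(cases, pop)
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in rows],
            "observed": [r.observed for r in rows],
            "expected": [r.expected for r in rows],
            "obs_over_exp": [r.obs_over_exp for r in rows],
            "relative_risk": [r.relative_risk for r in rows],
        }
    )
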