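import numpy as np
import pytest

from diarrscan import CasePanel, LocationTable, PopulationPanel


@pytest.fixture
def three_unit_locations():
    """Three collinear districts with equal base populations."""
    return LocationTable(
        unit_ids=("A", "B", "C"),
        names=("A", "B", "C"),
        lat=np.array([6.5, 6.6, 6.7]),
        lon=np.array([38.0, 38.0, 38.0]),
        base_population=np.array([1000.0, 1000.0, 1000.0]),
    )


@pytest.fixture
def small_panel(three_unit_locations):
    """3 units x 6 months with flat person-time and hand-set counts."""
    counts = np.array(
        [
            [5, 7, 6, 4, 8, 5],
            [6, 5, 7, 6, 5, 6],
            [4, 6, 5, 7, 6, 4],
        ]
    )
    pt = np.full((3, 6), 1000.0)
    return (
        CasePanel(three_unit_locations.unit_ids, counts),
        PopulationPanel(three_unit_locations.unit_ids, pt),
    )


def random_small_panel(rng, n_units=5, n_months=12):
    """A random panel for oracle-equivalence tests: random geometry,
    random person-time, Poisson counts with mildly heterogeneous rates."""
    ids = tuple(f"u{i}" for i in range(n_units))
    lat = rng.uniform(6.0, 7.5, n_units)
    lon = rng.uniform(38.0, 39.5, n_units)
    base = rng.uniform(500, 3000, n_units)
    loc = LocationTable(ids, ids, lat, lon, base)
    pt = base[:, None] * rng.uniform(0.9, 1.1, (n_units, n_months))
    rates = rng.uniform(0.005, 0.02, n_units)
    counts = rng.poisson(pt * rates[:, None])
    counts[0, 0] += 1  # guarantee a nonempty panel
    return CasePanel(ids, counts), PopulationPanel(ids, pt), loc
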