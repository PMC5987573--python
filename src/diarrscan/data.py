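"""Core domain containers and CSV / GeoJSON input-output.

The analysis operates on a rectangular district-by-month panel: every
geographic unit reports a nonnegative case count for every month of the
study period, and person-time denominators live on the same index.  The
containers here are deliberately thin wrappers around numpy arrays keyed
by unit id — scan-window arithmetic is interval arithmetic on integer
month indices, so months are stored 0-based from panel start and calendar
labels are metadata only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class PanelError(ValueError):
    """Raised when a panel violates its rectangular-index contract."""


@dataclass(frozen=True)
class LocationTable:
    """Point locations and base-year populations of the reporting units.

    Each unit is represented by a single representative coordinate
    (decimal degrees, WGS84 assumed) and its under-five population at
    panel start.
    """

    unit_ids: tuple[str, ...]
    names: tuple[str, ...]
    lat: np.ndarray
    lon: np.ndarray
    base_population: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        if len(set(self.unit_ids)) != n:
            raise PanelError("unit_id values must be unique")
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        pop = np.asarray(self.base_population, dtype=float)
        if not (len(self.names) == lat.size == lon.size == pop.size == n):
            raise PanelError("location table columns must have equal length")
        if np.any(lat < -90) or np.any(lat > 90):
            raise PanelError("latitude outside [-90, 90]")
        if np.any(lon < -180) or np.any(lon > 180):
            raise PanelError("longitude outside [-180, 180]")
        if np.any(pop <= 0):
            raise PanelError("base_population must be positive")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "base_population", pop)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit_id: str) -> int:
        try:
            return self.unit_ids.index(unit_id)
        except ValueError:
            raise KeyError(f"unknown unit_id: {unit_id!r}") from None

    @classmethod
    def from_csv(cls, path) -> "LocationTable":
        df = pd.read_csv(path, dtype={"unit_id": str, "name": str})
        required = {"unit_id", "name", "lat", "lon", "base_population"}
        missing = required - set(df.columns)
        if missing:
            raise PanelError(f"location CSV missing columns: {sorted(missing)}")
        return cls(
            unit_ids=tuple(df["unit_id"]),
            names=tuple(df["name"]),
            lat=df["lat"].to_numpy(float),
            lon=df["lon"].to_numpy(float),
            base_population=df["base_population"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "name": self.names,
                "lat": self.lat,
                "lon": self.lon,
                "base_population": self.base_population,
            }
        )


@dataclass(frozen=True)
class CasePanel:
    """Monthly case counts on a complete (unit, month) grid.

    ``counts[i, m]`` is the number of cases in unit ``unit_ids[i]`` during
    month ``m`` (0-based consecutive months from panel start).  The index
    must be complete: surveillance gaps are an error, never silently
    zero-filled.
    """

    unit_ids: tuple[str, ...]
    counts: np.ndarray
    month_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != len(self.unit_ids):
            raise PanelError("counts must be a (n_units, n_months) array")
        if np.any(counts < 0):
            raise PanelError("case counts must be nonnegative")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.floor(counts)):
                raise PanelError("case counts must be integers")
            counts = counts.astype(np.int64)
        if self.month_labels is not None and len(self.month_labels) != counts.shape[1]:
            raise PanelError("month_labels length must equal n_months")
        object.__setattr__(self, "counts", counts)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_months(self) -> int:
        return self.counts.shape[1]

    @property
    def total_cases(self) -> int:
        """C — the grand total over all cells."""
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns unit_id, month, count."""
        n_u, n_m = self.counts.shape
        months: Sequence = (
            self.month_labels if self.month_labels is not None else range(n_m)
        )
        return pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_ids, n_m),
                "month": list(months) * n_u,
                "count": self.counts.ravel(),
            }
        )


@dataclass(frozen=True)
class PopulationPanel:
    """Person-time denominators (person-months) on the same grid as cases."""

    unit_ids: tuple[str, ...]
    person_time: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.person_time, dtype=float)
        if pt.ndim != 2 or pt.shape[0] != len(self.unit_ids):
            raise PanelError("person_time must be a (n_units, n_months) array")
        if np.any(pt <= 0):
            raise PanelError("person_time entries must be positive")
        object.__setattr__(self, "person_time", pt)

    @property
    def n_units(self) -> int:
        return self.person_time.shape[0]

    @property
    def n_months(self) -> int:
        return self.person_time.shape[1]

    @property
    def total(self) -> float:
        """P — total person-time over all cells."""
        return float(self.person_time.sum())


def _parse_month(value) -> tuple[int, str | None]:
    """Return (sortable month number, label) for an integer index or ISO yyyy-mm."""
    s = str(value).strip()
    if s.lstrip("-").isdigit():
        return int(s), None
    try:
        period = pd.Period(s, freq="M")
    except Exception as exc:  # malformed date
        raise PanelError(f"unparseable month value: {value!r}") from exc
    return period.ordinal, str(period)


def read_case_panel(path, location_table: LocationTable) -> CasePanel:
    """Read a long-format case CSV into a rectangular :class:`CasePanel`.

    The CSV needs columns ``unit_id``, ``month`` (ISO yyyy-mm or integer
    index) and ``count``.  Months are re-indexed 0-based from the earliest
    month present.  Any hole in the (unit, month) grid is an error naming
    the missing cell.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    required = {"unit_id", "month", "count"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"case CSV missing columns: {sorted(missing)}")

    known = set(location_table.unit_ids)
    unknown = sorted(set(df["unit_id"]) - known)
    if unknown:
        raise KeyError(f"unknown unit_id values in case CSV: {unknown}")

    parsed = [_parse_month(v) for v in df["month"]]
    ordinals = np.array([p[0] for p in parsed])
    start = ordinals.min()
    month_idx = ordinals - start
    n_months = int(month_idx.max()) + 1

    labels: tuple[str, ...] | None = None
    if parsed and parsed[0][1] is not None:
        start_period = pd.Period(parsed[int(np.argmin(ordinals))][1], freq="M")
        labels = tuple(str(start_period + k) for k in range(n_months))

    counts_col = df["count"].to_numpy()
    if np.any(counts_col < 0):
        bad = df.loc[df["count"] < 0].iloc[0]
        raise PanelError(
            f"negative count for unit {bad['unit_id']!r}, month {bad['month']!r}"
        )

    unit_pos = {u: i for i, u in enumerate(location_table.unit_ids)}
    rows = np.array([unit_pos[u] for u in df["unit_id"]])

    seen = set(zip(rows.tolist(), month_idx.tolist()))
    if len(seen) != len(df):
        pairs = list(zip(df["unit_id"], df["month"]))
        dupes = {p for p in pairs if pairs.count(p) > 1}
        raise PanelError(f"duplicate (unit, month) records: {sorted(dupes)[:5]}")

    n_units = location_table.n_units
    if len(seen) != n_units * n_months:
        for i in range(n_units):
            for m in range(n_months):
                if (i, m) not in seen:
                    label = labels[m] if labels else m
                    raise PanelError(
                        "missing cell in case panel: unit "
                        f"{location_table.unit_ids[i]!r}, month {label}"
                    )

    counts = np.zeros((n_units, n_months), dtype=np.int64)
    counts[rows, month_idx] = counts_col
    return CasePanel(location_table.unit_ids, counts, month_labels=labels)


# --- GeoJSON export -------------------------------------------------------

def _circle_polygon(lon: float, lat: float, radius_deg: float, n_vertices: int = 64):
    """Circle approximated in raw degree space (the scan's distance metric)."""
    from shapely.geometry import Point, mapping

    if radius_deg <= 0:
        # degenerate single-point circle: tiny disc so the feature renders
        radius_deg = 1e-4
    return mapping(Point(lon, lat).buffer(radius_deg, quad_segs=n_vertices // 4))


def write_clusters_geojson(results, locations: LocationTable, path) -> None:
    """Write detected clusters as an RFC 7946 FeatureCollection (lon-lat).

    Spatial and space-time windows with a circular base become circle
    polygons; windows without a stored center/radius (e.g. purely temporal)
    become a MultiPoint of the member-unit coordinates.  All cluster
    statistics ride along as feature properties.
    """
    from shapely.geometry import MultiPoint, mapping

    features = []
    for res in results:
        w = res.window
        for u in w.member_units:
            if u not in locations.unit_ids:
                raise KeyError(f"cluster references unknown unit_id: {u!r}")
        if w.center_unit is not None and w.radius is not None:
            ci = locations.index_of(w.center_unit)
            geometry = _circle_polygon(
                float(locations.lon[ci]), float(locations.lat[ci]), float(w.radius)
            )
        else:
            pts = [
                (float(locations.lon[locations.index_of(u)]),
                 float(locations.lat[locations.index_of(u)]))
                for u in sorted(w.member_units)
            ]
            geometry = mapping(MultiPoint(pts))
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "kind": w.kind,
                    "member_units": sorted(w.member_units),
                    "month_start": w.month_range[0],
                    "month_end": w.month_range[1],
                    "center_unit": w.center_unit,
                    "radius": w.radius,
                    "observed": res.observed,
                    "expected": res.expected,
                    "obs_over_exp": res.obs_over_exp,
                    "relative_risk": res.relative_risk,
                    "llr": res.llr,
                    "p_value": res.p_value,
                    "rank": res.rank,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)
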