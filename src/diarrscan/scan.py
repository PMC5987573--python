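"""Discrete-Poisson scan statistic for spatial, temporal and space-time clusters.

Candidate clusters are circular collections of units (purely spatial),
contiguous month intervals over all units (purely temporal), or cylinders
combining a circular base with a month interval (space-time).  Each window
is scored by the Poisson window log-likelihood ratio

    LLR = c * ln(c / E) + (C - c) * ln((C - c) / (C - E))     if c > E

and 0 otherwise when scanning for high rates only, where c and E are the
observed and null-expected counts inside the window and C the panel total.
The window maximizing the LLR is the most likely cluster; its significance
comes from Monte Carlo replication of the panel under the conditional
Poisson null (C cases redistributed multinomially, cell probabilities
proportional to expected counts), ranking the observed maximum among the
replicate maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import CasePanel, LocationTable, PopulationPanel
from .risk import expected_counts


@dataclass(frozen=True)
class ScanWindow:
    """A candidate cluster: unit set x inclusive month interval."""

    kind: str  # "spatial" | "temporal" | "spacetime"
    member_units: tuple[str, ...]
    month_range: tuple[int, int]
    center_unit: str | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("spatial", "temporal", "spacetime"):
            raise ValueError(f"unknown window kind: {self.kind!r}")
        if not self.member_units:
            raise ValueError("window must contain at least one unit")
        s, e = self.month_range
        if s > e or s < 0:
            raise ValueError(f"invalid month_range: {self.month_range}")
        object.__setattr__(self, "member_units", tuple(sorted(self.member_units)))

    @property
    def n_months(self) -> int:
        return self.month_range[1] - self.month_range[0] + 1

    @property
    def n_cells(self) -> int:
        return len(self.member_units) * self.n_months


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the scan, mirroring standard surveillance practice.

    Defaults: circles capped at 50% of the population at risk, intervals
    capped at 50% of the study period, 1-month time aggregation, 999
    Monte Carlo replicates, high-rate clusters only, distances measured
    as Euclidean distance on raw decimal degrees.
    """

    max_spatial_population_fraction: float = 0.5
    max_temporal_fraction: float = 0.5
    time_aggregation: int = 1
    n_replicates: int = 999
    seed: int = 0
    high_rates_only: bool = True
    distance_metric: str = "cartesian_degrees"  # or "great_circle"

    def __post_init__(self) -> None:
        for f in (self.max_spatial_population_fraction, self.max_temporal_fraction):
            if not 0 < f <= 0.5:
                raise ValueError("scan caps must lie in (0, 0.5]")
        if self.n_replicates < 9:
            raise ValueError("need at least 9 Monte Carlo replicates")
        if self.distance_metric not in ("cartesian_degrees", "great_circle"):
            raise ValueError(f"unknown distance metric: {self.distance_metric!r}")


@dataclass(frozen=True)
class ClusterResult:
    window: ScanWindow
    observed: int
    expected: float
    obs_over_exp: float
    relative_risk: float
    llr: float
    p_value: float
    rank: int | None = None


def poisson_llr(c: float, expected: float, total_cases: float) -> float:
    """Poisson window log-likelihood ratio, high-rates indicator applied.

    Returns 0 whenever the window is not in excess (c <= E); the c = 0 and
    c = C boundary terms follow the x*ln(x) -> 0 limit.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if expected >= total_cases:
        raise ValueError("expected count must be below the panel total")
    if not 0 <= c <= total_cases:
        raise ValueError("observed count must lie in [0, total_cases]")
    if c <= expected:
        return 0.0
    out = c * math.log(c / expected)
    rem = total_cases - c
    if rem > 0:
        out += rem * math.log(rem / (total_cases - expected))
    return out


def window_relative_risk(c: float, expected: float, total_cases: float) -> float:
    """(c/E) / ((C-c)/(C-E)) — the window rate against the outside rate."""
    from .risk import relative_risk

    return relative_risk(c, expected, total_cases)


def _llr_vector(c: np.ndarray, E: np.ndarray, C: float, high_only: bool) -> np.ndarray:
    out = np.zeros_like(E, dtype=float)
    mask = (c > E) if high_only else (c != E)
    if not mask.any():
        return out
    cm = c[mask].astype(float)
    em = E[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(cm > 0, cm * np.log(cm / em), 0.0)
        rem = C - cm
        t2 = np.where(rem > 0, rem * np.log(rem / (C - em)), 0.0)
    out[mask] = t1 + t2
    return out


# --- window enumeration ---------------------------------------------------

def _pairwise_distances(locations: LocationTable, metric: str) -> np.ndarray:
    lat, lon = locations.lat, locations.lon
    if metric == "cartesian_degrees":
        d2 = (lat[:, None] - lat[None, :]) ** 2 + (lon[:, None] - lon[None, :]) ** 2
        return np.sqrt(d2)
    # haversine, kilometres
    rlat, rlon = np.radians(lat), np.radians(lon)
    dlat = rlat[:, None] - rlat[None, :]
    dlon = rlon[:, None] - rlon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(rlat)[:, None] * np.cos(rlat)[None, :] * np.sin(dlon / 2) ** 2
    return 6371.0 * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def enumerate_spatial_windows(
    locations: LocationTable, pop: PopulationPanel, config: ScanConfig
) -> list[ScanWindow]:
    """All distinct circles of nearest neighbours under the population cap.

    For every center unit, grow the circle one distance ring at a time
    (units at exactly tied distance enter together), stopping before the
    circle's person-time would exceed the configured fraction of the panel
    total.  Duplicate member sets arising from different centers are kept
    once (first center in unit-id order wins).
    """
    if locations.n_units < 1:
        raise ValueError("need at least one location")
    pt_unit = pop.person_time.sum(axis=1)
    cap = config.max_spatial_population_fraction * pt_unit.sum()
    dist = _pairwise_distances(locations, config.distance_metric)

    seen: dict[frozenset, ScanWindow] = {}
    order_ids = np.array(locations.unit_ids)
    for ci in range(locations.n_units):
        d = dist[ci]
        # stable order: distance, then unit_id for deterministic ties
        order = np.lexsort((order_ids, d))
        members: list[int] = []
        cum = 0.0
        j = 0
        while j < len(order):
            # pull the whole tie ring at once
            ring = [order[j]]
            j += 1
            while j < len(order) and d[order[j]] == d[ring[0]]:
                ring.append(order[j])
                j += 1
            ring_pt = pt_unit[ring].sum()
            if cum + ring_pt > cap:
                break
            members.extend(ring)
            cum += ring_pt
            key = frozenset(members)
            if key not in seen:
                seen[key] = ScanWindow(
                    kind="spatial",
                    member_units=tuple(str(order_ids[k]) for k in members),
                    month_range=(0, pop.n_months - 1),
                    center_unit=locations.unit_ids[ci],
                    radius=float(d[members[-1]]),
                )
    return list(seen.values())


def enumerate_temporal_windows(n_months: int, config: ScanConfig) -> list[tuple[int, int]]:
    """All inclusive month intervals no longer than the temporal cap."""
    if n_months < 2:
        raise ValueError("need at least two months")
    max_len = int(math.floor(config.max_temporal_fraction * n_months))
    if max_len < 1:
        raise ValueError("temporal cap admits no window")
    return [
        (s, s + length - 1)
        for length in range(1, max_len + 1)
        for s in range(n_months - length + 1)
    ]


def temporal_scan_windows(
    unit_ids: tuple[str, ...], n_months: int, config: ScanConfig
) -> list[ScanWindow]:
    """Temporal intervals wrapped as all-unit scan windows."""
    return [
        ScanWindow(kind="temporal", member_units=tuple(unit_ids), month_range=rng)
        for rng in enumerate_temporal_windows(n_months, config)
    ]


def enumerate_spacetime_windows(
    locations: LocationTable,
    pop: PopulationPanel,
    n_months: int,
    config: ScanConfig,
) -> list[ScanWindow]:
    """Cylinders: every admissible circle crossed with every admissible interval."""
    bases = enumerate_spatial_windows(locations, pop, config)
    if n_months == 1:
        ranges = [(0, 0)]
    else:
        ranges = enumerate_temporal_windows(n_months, config)
    return [
        replace(base, kind="spacetime", month_range=rng)
        for base in bases
        for rng in ranges
    ]


# --- the scan itself ------------------------------------------------------

def _compile_windows(windows, unit_ids):
    """Group windows into shared spatial bases + per-window month ranges."""
    unit_pos = {u: i for i, u in enumerate(unit_ids)}
    base_index: dict[frozenset, int] = {}
    bases: list[list[int]] = []
    w_base = np.empty(len(windows), dtype=np.int64)
    w_s = np.empty(len(windows), dtype=np.int64)
    w_e = np.empty(len(windows), dtype=np.int64)
    for k, w in enumerate(windows):
        try:
            key = frozenset(unit_pos[u] for u in w.member_units)
        except KeyError as exc:
            raise KeyError(f"window references unknown unit_id: {exc.args[0]!r}") from None
        bid = base_index.get(key)
        if bid is None:
            bid = len(bases)
            base_index[key] = bid
            bases.append(sorted(key))
        w_base[k] = bid
        w_s[k], w_e[k] = w.month_range
    B = np.zeros((len(bases), len(unit_ids)))
    for bid, members in enumerate(bases):
        B[bid, members] = 1.0
    return B, w_base, w_s, w_e


def _window_sums(B, w_base, w_s, w_e, X):
    """Sum of X over each window's cells via per-base month cumsums."""
    S = B @ X  # (n_bases, n_months)
    cum = np.concatenate([np.zeros((S.shape[0], 1)), np.cumsum(S, axis=1)], axis=1)
    return cum[w_base, w_e + 1] - cum[w_base, w_s]


def scan(
    cases: CasePanel,
    pop: PopulationPanel,
    windows: list[ScanWindow],
    config: ScanConfig,
    rng: np.random.Generator | None = None,
) -> list[ClusterResult]:
    """Score every window, rank by LLR, attach Monte Carlo p-values.

    The null distribution of the maximum LLR is simulated by redistributing
    the C observed cases over all cells of the panel, multinomially with
    probabilities E(cell)/C, and rescanning each replicate over the same
    window family.  p(window) = (1 + #{replicate maxima >= LLR}) /
    (1 + n_replicates), so the smallest attainable p with 999 replicates
    is 0.001.

    Windows that are not in excess (LLR = 0) are dropped from the result;
    ties in LLR break toward the smaller window, then lexicographically.
    """
    if not windows:
        raise ValueError("window list is empty")
    C = cases.total_cases
    if C == 0:
        raise ValueError("case panel contains no cases")
    E = expected_counts(cases, pop)

    B, w_base, w_s, w_e = _compile_windows(windows, cases.unit_ids)
    E_w = _window_sums(B, w_base, w_s, w_e, E)
    if np.any(E_w >= C):
        raise ValueError("a window covers the whole panel's expectation; tighten caps")
    c_w = _window_sums(B, w_base, w_s, w_e, cases.counts.astype(float))
    llr_w = _llr_vector(c_w, E_w, C, config.high_rates_only)

    if rng is None:
        rng = np.random.default_rng(config.seed)
    probs = (E / C).ravel()
    probs = probs / probs.sum()  # guard float drift in multinomial
    shape = cases.counts.shape
    rep_max = np.empty(config.n_replicates)
    for r in range(config.n_replicates):
        Xr = rng.multinomial(C, probs).reshape(shape).astype(float)
        cr = _window_sums(B, w_base, w_s, w_e, Xr)
        rep_max[r] = _llr_vector(cr, E_w, C, config.high_rates_only).max()
    rep_sorted = np.sort(rep_max)

    keep = np.flatnonzero(llr_w > 0)
    # p = (1 + #{rep max >= llr}) / (R + 1)
    exceed = config.n_replicates - np.searchsorted(rep_sorted, llr_w[keep], side="left")
    p_vals = (1.0 + exceed) / (1.0 + config.n_replicates)

    order = sorted(
        range(keep.size),
        key=lambda i: (
            -llr_w[keep[i]],
            windows[keep[i]].n_cells,
            windows[keep[i]].member_units,
            windows[keep[i]].month_range,
        ),
    )
    results = []
    for rank, i in enumerate(order, start=1):
        k = keep[i]
        c, e = float(c_w[k]), float(E_w[k])
        rr = (c / e) / ((C - c) / (C - e)) if C - c > 0 else float("inf")
        results.append(
            ClusterResult(
                window=windows[k],
                observed=int(round(c)),
                expected=e,
                obs_over_exp=c / e,
                relative_risk=rr,
                llr=float(llr_w[k]),
                p_value=float(p_vals[i]),
                rank=rank,
            )
        )
    return results


def report_clusters(
    results: list[ClusterResult],
    alpha: float = 0.05,
    overlap_policy: str = "no_shared_units",
) -> list[ClusterResult]:
    """Primary + secondary clusters: greedy non-overlapping selection.

    Walk the LLR-ranked results; keep a window only if it is significant
    and disjoint from everything already kept — sharing no member unit
    (spatial / space-time windows) or no month (temporal windows).  Ranks
    are reassigned 1..k in report order.
    """
    if overlap_policy != "no_shared_units":
        raise ValueError(f"unknown overlap policy: {overlap_policy!r}")
    reported: list[ClusterResult] = []
    used_units: set[str] = set()
    used_months: set[int] = set()
    for res in results:
        if res.p_value >= alpha:
            continue
        w = res.window
        if w.kind == "temporal":
            months = set(range(w.month_range[0], w.month_range[1] + 1))
            if months & used_months:
                continue
            used_months |= months
        else:
            if set(w.member_units) & used_units:
                continue
            used_units |= set(w.member_units)
        reported.append(replace(res, rank=len(reported) + 1))
    return reported
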