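"""End-to-end orchestration: panels in, tables + cluster reports out.

One call runs the full surveillance analysis in the order a zonal health
analyst would: yearly incidence rates, seasonal-trend decomposition of the
zone-wide monthly rate, the per-district excess-risk table, and the three
scans (purely spatial, purely temporal, space-time) with Monte Carlo
inference, writing CSV / JSON / GeoJSON artifacts plus a manifest that
pins seed, config and package version for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import CasePanel, LocationTable, PopulationPanel, read_case_panel, write_clusters_geojson
from .demography import ProjectionConfig, monthly_population_panel, yearly_rate_table
from .risk import excess_risk_frame
from .scan import (
    ScanConfig,
    enumerate_spacetime_windows,
    enumerate_spatial_windows,
    report_clusters,
    scan,
    temporal_scan_windows,
)
from .seasonality import seasonal_decompose

log = logging.getLogger("diarrscan")


@dataclass(frozen=True)
class PipelineConfig:
    case_csv: str
    location_csv: str
    out_dir: str
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    log_level: str = "INFO"


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan one user seed out to independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _cluster_frame(results, locations: LocationTable, month_labels) -> pd.DataFrame:
    def label(m):
        return month_labels[m] if month_labels else m

    rows = []
    for r in results:
        rows.append(
            {
                "rank": r.rank,
                "units": ";".join(r.window.member_units),
                "center_unit": r.window.center_unit,
                "radius": r.window.radius,
                "start": label(r.window.month_range[0]),
                "end": label(r.window.month_range[1]),
                "observed": r.observed,
                "expected": round(r.expected, 2),
                "obs_over_exp": round(r.obs_over_exp, 4),
                "relative_risk": round(r.relative_risk, 4),
                "llr": round(r.llr, 4),
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "units", "center_unit", "radius", "start", "end",
            "observed", "expected", "obs_over_exp", "relative_risk",
            "llr", "p_value",
        ],
    )


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns their paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    locations = LocationTable.from_csv(config.location_csv)
    cases = read_case_panel(config.case_csv, locations)
    pop = monthly_population_panel(locations, config.projection, cases.n_months)
    log.info(
        "loaded panel: %d units x %d months, %d cases",
        cases.n_units, cases.n_months, cases.total_cases,
    )
    artifacts: dict[str, str] = {}

    # yearly incidence rates (per 1000)
    if cases.n_months >= 12:
        rates = yearly_rate_table(cases, pop)
        rates.to_csv(out / "yearly_rates.csv")
        artifacts["yearly_rates"] = str(out / "yearly_rates.csv")

    # zone-wide monthly rate per 1000 -> seasonal decomposition
    if cases.n_months >= 24:
        monthly_rate = cases.counts.sum(axis=0) / pop.person_time.sum(axis=0) * 1000.0
        fit = seasonal_decompose(monthly_rate)
        with open(out / "seasonal_fit.json", "w") as fh:
            json.dump(
                {
                    "seasonal_index": fit.seasonal_index.tolist(),
                    "trend_slope": fit.trend_slope,
                    "trend_intercept": fit.trend_intercept,
                    "smoothed": fit.smoothed.tolist(),
                },
                fh,
                indent=1,
            )
        artifacts["seasonal_fit"] = str(out / "seasonal_fit.json")
    else:
        log.warning("panel shorter than 24 months; seasonal stage skipped")

    # excess-risk table (degenerate on a single unit: E = C, RR undefined)
    if cases.n_units >= 2:
        risk = excess_risk_frame(cases, pop)
        risk.to_csv(out / "excess_risk.csv", index=False)
        artifacts["excess_risk"] = str(out / "excess_risk.csv")
    else:
        log.warning("single-unit panel: excess-risk table skipped")

    # scans
    seeds = _child_seeds(config.scan.seed, 3)
    labels = cases.month_labels
    if cases.n_units >= 2:
        for mode, seed in zip(("spatial", "spacetime"), seeds[:2]):
            cfg = replace(config.scan, seed=seed)
            if mode == "spatial":
                windows = enumerate_spatial_windows(locations, pop, cfg)
            else:
                windows = enumerate_spacetime_windows(locations, pop, cases.n_months, cfg)
            if not windows:
                log.warning("%s scan skipped: no admissible window under caps", mode)
                continue
            t = time.time()
            results = scan(cases, pop, windows, cfg)
            reported = report_clusters(results)
            log.info("%s scan: %d clusters reported (%.1fs)", mode, len(reported), time.time() - t)
            _cluster_frame(reported, locations, labels).to_csv(
                out / f"clusters_{mode}.csv", index=False
            )
            write_clusters_geojson(reported, locations, out / f"clusters_{mode}.geojson")
            artifacts[f"clusters_{mode}"] = str(out / f"clusters_{mode}.csv")
    else:
        log.warning("single-unit panel: spatial and space-time scans skipped")

    if cases.n_months >= 2:
        cfg = replace(config.scan, seed=seeds[2])
        windows = temporal_scan_windows(cases.unit_ids, cases.n_months, cfg)
        results = scan(cases, pop, windows, cfg)
        reported = report_clusters(results)
        log.info("temporal scan: %d clusters reported", len(reported))
        _cluster_frame(reported, locations, labels).to_csv(
            out / "clusters_temporal.csv", index=False
        )
        artifacts["clusters_temporal"] = str(out / "clusters_temporal.csv")
    else:
        log.warning("single-month panel: temporal scan skipped")

    manifest = {
        "seed": config.scan.seed,
        "stage_seeds": seeds,
        "config": {
            "projection": asdict(config.projection),
            "scan": asdict(config.scan),
        },
        "config_hash": hashlib.sha256(
            json.dumps(
                {"projection": asdict(config.projection), "scan": asdict(config.scan)},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "version": __version__,
        "n_units": cases.n_units,
        "n_months": cases.n_months,
        "total_cases": cases.total_cases,
        "artifacts": artifacts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
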