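"""Window likelihoods, window enumeration, the scan and cluster reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diarrscan import (
    CasePanel,
    ClusterResult,
    LocationTable,
    PopulationPanel,
    ScanConfig,
    ScanWindow,
    enumerate_spacetime_windows,
    enumerate_spatial_windows,
    enumerate_temporal_windows,
    poisson_llr,
    report_clusters,
    scan,
    temporal_scan_windows,
    window_relative_risk,
)

from conftest import random_small_panel
from oracle import best_window, llr_direct

C_STUDY = 202_406


class TestPoissonLLR:
    # published cluster statistics: (observed, expected, LLR, RR)
    PUBLISHED = [
        (29_153, 17_146.87, 3864.33, 1.82),
        (11_952, 7_522.60, 1154.94, 1.63),
        (13_335, 8_856.59, 1030.89, 1.54),
        (19_636, 16_027.43, 413.94, 1.25),
        (16_005, 12_947.92, 360.24, 1.26),
        (17_713, 16_626.00, 37.97, 1.07),
        (7_351, 6_799.06, 22.60, 1.08),
        (63_683, 50_695.23, 2109.93, 1.37),
        (6_186, 3_097.21, 1214.67, 2.03),
        (900, 441.07, 183.47, 2.05),
        (327, 93.27, 176.61, 3.51),
        (479, 199.43, 140.34, 2.41),
        (216, 81.28, 76.44, 2.66),
    ]

    @pytest.mark.parametrize("c,E,llr,rr", PUBLISHED)
    def test_reproduces_published_cluster_llrs(self, c, E, llr, rr):
        assert poisson_llr(c, E, C_STUDY) == pytest.approx(llr, abs=0.5)

    @pytest.mark.parametrize("c,E,llr,rr", PUBLISHED)
    def test_reproduces_published_relative_risks(self, c, E, llr, rr):
        assert window_relative_risk(c, E, C_STUDY) == pytest.approx(rr, abs=0.01)

    def test_zero_at_the_null(self):
        assert poisson_llr(100, 100.0, 1000) == 0.0
        assert poisson_llr(50, 100.0, 1000) == 0.0  # deficit windows score 0
        assert window_relative_risk(100, 100.0, 1000) == pytest.approx(1.0)

    def test_boundary_c_equals_C(self):
        # all cases in the window: the (C-c)ln(...) term vanishes
        assert poisson_llr(10, 2.0, 10) == pytest.approx(10 * math.log(5.0))

    @pytest.mark.parametrize("c,E,C", [(1, 0.0, 10), (1, -1.0, 10), (5, 10.0, 8), (11, 5.0, 10)])
    def test_domain_errors(self, c, E, C):
        with pytest.raises(ValueError):
            poisson_llr(c, E, C)

    @settings(max_examples=60, derandomize=True)
    @given(E=st.floats(1.0, 400.0), C=st.integers(500, 5000))
    def test_strictly_increasing_in_c_above_E(self, E, C):
        cs = np.arange(int(E) + 1, int(E) + 50)
        vals = [poisson_llr(int(c), E, C) for c in cs]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestEnumeration:
    def test_singletons_only_under_tight_equal_population_cap(
        self, three_unit_locations
    ):
        # 3 equal units: any 2-unit circle holds 2/3 > 50% of person-time
        pop = PopulationPanel(("A", "B", "C"), np.full((3, 6), 1000.0))
        wins = enumerate_spatial_windows(
            three_unit_locations, pop, ScanConfig()
        )
        assert sorted(w.member_units for w in wins) == [("A",), ("B",), ("C",)]

    def test_nineteen_equal_units_max_window_size_nine(self):
        rng = np.random.default_rng(5)
        ids = tuple(f"u{i:02d}" for i in range(19))
        loc = LocationTable(
            ids, ids, rng.uniform(6, 7, 19), rng.uniform(38, 39, 19), np.ones(19)
        )
        pop = PopulationPanel(ids, np.ones((19, 12)))
        wins = enumerate_spatial_windows(loc, pop, ScanConfig())
        sizes = {len(w.member_units) for w in wins}
        assert max(sizes) == 9  # floor(0.5 * 19)
        assert 1 in sizes  # every singleton is a candidate

    def test_member_sets_are_deduplicated(self):
        ids = ("A", "B")
        loc = LocationTable(ids, ids, [6.0, 6.1], [38.0, 38.0], [1.0, 1.0])
        pop = PopulationPanel(ids, np.ones((2, 4)))
        wins = enumerate_spatial_windows(loc, pop, ScanConfig())
        assert len({frozenset(w.member_units) for w in wins}) == len(wins)

    def test_tied_distances_enter_together(self):
        # B and C equidistant from A; a circle from A either has both or neither
        ids = ("A", "B", "C", "D")
        loc = LocationTable(
            ids, ids, [6.0, 6.1, 5.9, 6.0], [38.0, 38.0, 38.0, 38.5],
            [1.0, 1.0, 1.0, 1.0],
        )
        pop = PopulationPanel(ids, np.ones((4, 4)) * 100)
        wins = enumerate_spatial_windows(
            loc, pop, ScanConfig(max_spatial_population_fraction=0.5)
        )
        a_centered = [set(w.member_units) for w in wins if w.center_unit == "A"]
        assert a_centered  # the singleton {A} at least
        for m in a_centered:
            assert ("B" in m) == ("C" in m), "distance tie split within a circle"

    def test_temporal_window_count_small_case(self):
        wins = enumerate_temporal_windows(4, ScanConfig())
        assert len(wins) == 7  # 4 singletons + 3 pairs
        assert all(e - s + 1 <= 2 for s, e in wins)

    def test_temporal_cap_on_study_period(self):
        wins = enumerate_temporal_windows(72, ScanConfig())
        assert max(e - s + 1 for s, e in wins) == 36
        assert (29, 46) in wins  # an 18-month window is admissible

    def test_temporal_cap_admitting_nothing_is_an_error(self):
        with pytest.raises(ValueError, match="no window"):
            enumerate_temporal_windows(2, ScanConfig(max_temporal_fraction=0.25))

    def test_spacetime_two_by_two(self):
        ids = ("A", "B")
        loc = LocationTable(ids, ids, [6.0, 6.5], [38.0, 38.0], [1.0, 1.0])
        pop = PopulationPanel(ids, np.ones((2, 2)))
        wins = enumerate_spacetime_windows(loc, pop, 2, ScanConfig())
        keys = {(w.member_units, w.month_range) for w in wins}
        assert keys == {
            (("A",), (0, 0)), (("A",), (1, 1)),
            (("B",), (0, 0)), (("B",), (1, 1)),
        }

    def test_single_month_panel_reduces_to_spatial(self, three_unit_locations):
        pop = PopulationPanel(("A", "B", "C"), np.full((3, 1), 100.0))
        wins = enumerate_spacetime_windows(three_unit_locations, pop, 1, ScanConfig())
        assert all(w.month_range == (0, 0) for w in wins)
        assert len(wins) == 3


class TestScan:
    def test_matches_brute_force_on_small_panels(self):
        # spot check here; the exhaustive 100-panel sweep lives in the
        # acceptance suite
        rng = np.random.default_rng(17)
        for trial in range(5):
            cases, pop, loc = random_small_panel(rng)
            cfg = ScanConfig(n_replicates=9, seed=trial)
            for mode in ("spatial", "temporal", "spacetime"):
                if mode == "spatial":
                    wins = enumerate_spatial_windows(loc, pop, cfg)
                elif mode == "temporal":
                    wins = temporal_scan_windows(cases.unit_ids, cases.n_months, cfg)
                else:
                    wins = enumerate_spacetime_windows(loc, pop, cases.n_months, cfg)
                res = scan(cases, pop, wins, cfg)
                ref_llr, ref_argmax = best_window(
                    cases, pop, mode, loc=loc
                )
                if not res:
                    assert ref_llr == pytest.approx(0.0, abs=1e-9)
                    continue
                top = res[0]
                assert top.llr == pytest.approx(ref_llr, rel=1e-9)
                unit_pos = {u: i for i, u in enumerate(cases.unit_ids)}
                got = (
                    frozenset(unit_pos[u] for u in top.window.member_units),
                    top.window.month_range,
                )
                assert got in ref_argmax

    def test_llr_invariant_to_person_time_scaling(self, three_unit_locations):
        rng = np.random.default_rng(3)
        cases = CasePanel(("A", "B", "C"), rng.poisson(8, (3, 6)))
        pop = PopulationPanel(("A", "B", "C"), np.full((3, 6), 500.0))
        cfg = ScanConfig(n_replicates=9, seed=0)
        wins = enumerate_spatial_windows(three_unit_locations, pop, cfg)
        res1 = scan(cases, pop, wins, cfg)
        pop2 = PopulationPanel(pop.unit_ids, pop.person_time * 13.0)
        res2 = scan(cases, pop2, wins, cfg)
        assert [r.llr for r in res1] == pytest.approx([r.llr for r in res2])

    def test_p_values_on_the_replicate_grid(self):
        rng = np.random.default_rng(23)
        cases, pop, loc = random_small_panel(rng)
        cfg = ScanConfig(n_replicates=99, seed=5)
        res = scan(cases, pop, enumerate_spatial_windows(loc, pop, cfg), cfg)
        for r in res:
            assert 1 / 100 <= r.p_value <= 1.0
            assert (r.p_value * 100) == pytest.approx(round(r.p_value * 100))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(29)
        cases, pop, loc = random_small_panel(rng)
        cfg = ScanConfig(n_replicates=49, seed=77)
        wins = enumerate_spatial_windows(loc, pop, cfg)
        r1 = scan(cases, pop, wins, cfg)
        r2 = scan(cases, pop, wins, cfg)
        assert [(a.llr, a.p_value) for a in r1] == [(b.llr, b.p_value) for b in r2]

    def test_all_zero_panel_rejected(self, three_unit_locations):
        cases = CasePanel(("A", "B", "C"), np.zeros((3, 6), dtype=int))
        pop = PopulationPanel(("A", "B", "C"), np.full((3, 6), 100.0))
        cfg = ScanConfig(n_replicates=9)
        wins = enumerate_spatial_windows(three_unit_locations, pop, cfg)
        with pytest.raises(ValueError, match="no cases"):
            scan(cases, pop, wins, cfg)

    def test_empty_window_list_rejected(self, small_panel):
        cases, pop = small_panel
        with pytest.raises(ValueError, match="empty"):
            scan(cases, pop, [], ScanConfig(n_replicates=9))


def _mk_result(units, months, llr, p, kind="spatial"):
    w = ScanWindow(kind=kind, member_units=units, month_range=months)
    return ClusterResult(
        window=w, observed=10, expected=5.0, obs_over_exp=2.0,
        relative_risk=2.0, llr=llr, p_value=p,
    )


class TestReportClusters:
    def test_overlapping_windows_keep_higher_llr_only(self):
        res = [
            _mk_result(("A", "B"), (0, 5), 10.0, 0.001),
            _mk_result(("B", "C"), (0, 5), 8.0, 0.001),
            _mk_result(("D",), (0, 5), 5.0, 0.001),
        ]
        rep = report_clusters(res)
        assert [r.window.member_units for r in rep] == [("A", "B"), ("D",)]
        assert [r.rank for r in rep] == [1, 2]

    def test_insignificant_clusters_dropped(self):
        res = [
            _mk_result(("A",), (0, 5), 10.0, 0.001),
            _mk_result(("B",), (0, 5), 2.0, 0.4),
        ]
        assert len(report_clusters(res)) == 1

    def test_temporal_overlap_is_by_months(self):
        res = [
            _mk_result(("A", "B"), (3, 8), 9.0, 0.001, kind="temporal"),
            _mk_result(("A", "B"), (8, 10), 7.0, 0.001, kind="temporal"),
            _mk_result(("A", "B"), (9, 11), 6.0, 0.001, kind="temporal"),
        ]
        rep = report_clusters(res)
        assert [r.window.month_range for r in rep] == [(3, 8), (9, 11)]
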