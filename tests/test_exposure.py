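"""Study-universe selection and block-group exposure outcomes."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from coastrisk.exposure import (
    BlockGroup,
    blockgroup_exposure,
    exposure_table,
    populated_cells,
    select_coastal_blockgroups,
    select_study_counties,
)
from coastrisk.grid import Grid


def bg(bg_id="BG0", county="C0", geom=None, pop=100.0):
    return BlockGroup(bg_id, county, geom or box(0, 0, 1000, 1000), pop)


def risk_df(rows):
    return pd.DataFrame(rows, columns=["site_id", "category", "scenario", "year",
                                       "expected_floods", "p_annual", "at_risk"])


class TestStudyCounties:
    counties = {"C0": box(0, 0, 1000, 1000), "C1": box(1000, 0, 2000, 1000)}

    def test_county_without_at_risk_sites_excluded(self):
        fp = {"S1": Point(500, 500), "S2": Point(1500, 500)}
        risk = risk_df([
            ("S1", "refinery", "RCP85", 2100, 0.2, 0.18, True),
            ("S2", "refinery", "RCP85", 2100, 0.001, 0.001, False),
        ])
        assert select_study_counties(self.counties, fp, risk) == {"C0"}

    def test_single_at_risk_well_suffices(self):
        fp = {"W": Point(1500, 500)}
        risk = risk_df([("W", "oil_gas_well", "RCP85", 2100, 0.05, 0.05, True)])
        assert select_study_counties(self.counties, fp, risk) == {"C1"}

    def test_empty_risk_table_empty_set(self):
        assert select_study_counties(self.counties, {}, risk_df([])) == set()


class TestCoastalBlockgroups:
    def _dem(self):
        # 3 columns x 1 row, 1000 m cells: elevations 5 (low), 12, 20
        return Grid(values=np.array([[5.0, 12.0, 20.0]]), xmin=0, ymin=0, cell=1000.0)

    def test_distance_threshold_respected(self):
        dem = self._dem()
        # 10-m line is the boundary of cell [0,1000); polygon edge at x=1000
        near = bg("NEAR", "C0", box(3500, 0, 3900, 1000))   # 2500 m from edge
        far = bg("FAR", "C0", box(4100, 0, 4500, 1000))     # 3100 m from edge
        out = select_coastal_blockgroups([near, far], dem, {"C0"})
        assert [b.bg_id for b in out] == ["NEAR"]

    def test_county_gate_applies_first(self):
        dem = self._dem()
        close = bg("X", "C9", box(1100, 0, 1500, 1000))
        assert select_coastal_blockgroups([close], dem, {"C0"}) == []

    def test_no_low_land_is_error(self):
        dem = Grid(values=np.full((2, 2), 25.0), xmin=0, ymin=0, cell=1000.0)
        with pytest.raises(ValueError, match="coastal"):
            select_coastal_blockgroups([bg()], dem, {"C0"})


class TestPopulatedCells:
    def test_all_zero_raster_empty(self):
        grid = Grid(values=np.zeros((4, 4)), xmin=0, ymin=0, cell=250.0)
        out = populated_cells(bg(), grid)
        assert isinstance(out, np.ndarray) and len(out) == 0

    def test_fallback_returns_polygon(self):
        b = bg()
        assert populated_cells(b, None) is b.geometry

    def test_straddling_cell_center_outside_excluded(self):
        # polygon covers x in [0, 400): cell centers at 125, 375, 625, 875
        grid = Grid(values=np.ones((1, 4)), xmin=0, ymin=0, cell=250.0)
        b = bg(geom=box(0, 0, 400, 250))
        out = populated_cells(b, grid)
        assert sorted(out[:, 0].tolist()) == [125.0, 375.0]


class TestBlockgroupExposure:
    def test_distance_thresholds_and_radius(self):
        grid = Grid(values=np.ones((1, 1)), xmin=0, ymin=0, cell=100.0)  # center (50,50)
        b = bg(geom=box(0, 0, 100, 100))
        near = ("S1", Point(50, 1049), 0.05)     # 999 m from the populated cell
        mid = ("S2", Point(50, 1550), 0.02)      # 1500 m
        rec1 = blockgroup_exposure(b, [near, mid], 1000.0, grid)
        assert rec1["exposed"] and rec1["n_sites"] == 1
        assert rec1["eae"] == pytest.approx(0.05)
        rec3 = blockgroup_exposure(b, [near, mid], 3000.0, grid)
        assert rec3["n_sites"] == 2
        assert rec3["eae"] == pytest.approx(0.07)

    def test_distance_measured_to_footprint_edge(self):
        grid = Grid(values=np.ones((1, 1)), xmin=0, ymin=0, cell=100.0)
        b = bg(geom=box(0, 0, 100, 100))
        # polygon whose edge is 900 m away although its centroid is 1400 m away
        poly = box(-500, 950, 500, 1950)
        rec = blockgroup_exposure(b, [("S", poly, 0.02)], 1000.0, grid)
        assert rec["exposed"]

    def test_fallback_polygon_mode(self):
        b = bg(geom=box(0, 0, 100, 100))
        rec = blockgroup_exposure(b, [("S", Point(100, 1099), 0.02)], 1000.0, None)
        assert rec["exposed"]

    def test_site_counted_once_despite_many_cells(self):
        grid = Grid(values=np.ones((5, 5)), xmin=0, ymin=0, cell=100.0)
        b = bg(geom=box(0, 0, 500, 500))
        rec = blockgroup_exposure(b, [("S", Point(250, 600), 0.02)], 1000.0, grid)
        assert rec["n_sites"] == 1

    def test_brute_force_distance_oracle(self):
        """n_sites must equal a naive all-pairs distance computation."""
        rng = np.random.default_rng(0)
        grid = Grid(values=(rng.random((10, 10)) < 0.4).astype(float),
                    xmin=0, ymin=0, cell=100.0)
        sites = [(f"S{i}", Point(rng.uniform(0, 1000), rng.uniform(0, 1000)),
                  float(rng.uniform(0.01, 0.5))) for i in range(20)]
        for _ in range(10):
            x0, y0 = rng.uniform(0, 700, size=2)
            b = bg(geom=box(x0, y0, x0 + 300, y0 + 300))
            cells = populated_cells(b, grid)
            for radius in (200.0, 500.0):
                rec = blockgroup_exposure(b, sites, radius, grid)
                brute = 0
                for _, p, _ in sites:
                    if len(cells) and min(
                        np.hypot(cells[:, 0] - p.x, cells[:, 1] - p.y)
                    ) <= radius:
                        brute += 1
                assert rec["n_sites"] == brute


@pytest.fixture(scope="module")
def expo(region):
    from coastrisk.pipeline import run_pipeline
    import tempfile

    with tempfile.TemporaryDirectory() as td:
        run_pipeline(region=region, out_dir=td, n_boot=100)
        return pd.read_csv(f"{td}/exposure.csv")


class TestRegionExposureInvariants:
    def test_radius_monotonicity(self, expo):
        for (bgid, scen, yr), grp in expo.groupby(["bg_id", "scenario", "year"]):
            by_r = grp.set_index("radius_m")
            assert by_r.loc[3000.0, "n_sites"] >= by_r.loc[1000.0, "n_sites"]
            assert by_r.loc[3000.0, "eae"] >= by_r.loc[1000.0, "eae"] - 1e-12

    def test_eae_bounds(self, expo):
        assert (expo["eae"] >= 0.01 * expo["n_sites"] - 1e-12).all()
        assert (expo["eae"] <= expo["n_sites"] + 1e-12).all()
        assert (expo["exposed"] == (expo["n_sites"] >= 1)).all()

    def test_scenario_monotonicity_2100(self, expo):
        """RCP 8.5 SLR stochastically dominates RCP 4.5 by construction, so
        exposure under 4.5 implies exposure under 8.5 at 2100."""
        p45 = expo[(expo["scenario"] == "RCP45") & (expo["year"] == 2100)]
        p85 = expo[(expo["scenario"] == "RCP85") & (expo["year"] == 2100)]
        merged = p45.merge(p85, on=["bg_id", "radius_m"], suffixes=("_45", "_85"))
        assert (~merged["exposed_45"] | merged["exposed_85"]).all()

    def test_exposure_table_rejects_mixed_scenarios(self, region):
        mixed = pd.DataFrame(
            {
                "site_id": ["A", "B"],
                "scenario": ["RCP45", "RCP85"],
                "year": [2100, 2100],
                "p_annual": [0.1, 0.1],
                "at_risk": [True, True],
            }
        )
        with pytest.raises(ValueError):
            exposure_table([], mixed, {})
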