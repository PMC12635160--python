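"""Site-cleaning rules: filtering, categories, dedupe, footprints, FUDS."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from coastrisk.grid import Grid
from coastrisk.ingest import (
    DEFAULT_RULEBOOK,
    HazardSite,
    RawSiteRecord,
    Rule,
    RulebookError,
    address_similarity,
    assign_footprint,
    categorize,
    clip_to_coast,
    dedupe,
    exclude_offshore_wells,
    filter_records,
    overlap_ratio,
    resolve_fuds,
    site_elevation,
)


def rec(record_id="R1", address="123 MAIN ST", x=100.0, y=100.0, **kw):
    return RawSiteRecord(record_id=record_id, source="T", address=address, x=x, y=y, **kw)


class TestFilter:
    def test_imprecise_location_dropped(self):
        assert filter_records([rec(accuracy_m=60.0)]) == []

    def test_precise_record_kept(self):
        assert len(filter_records([rec(accuracy_m=50.0)])) == 1

    def test_inactive_expired_permit_retained(self):
        r = rec(active=False, accuracy_m=10.0, end_year=2035)
        assert filter_records([r]) == [r]

    def test_end_dated_and_remediated_dropped(self):
        assert filter_records([rec(end_year=2020), rec(remediated=True), rec(zip_level=True)]) == []

    def test_empty_input(self):
        assert filter_records([]) == []


class TestCategorize:
    def test_priority_resolves_multi_permit_records(self):
        # refinery industry code plus a generic TRI permit: refinery wins
        r = rec(hints=("NAICS:32411", "TRI"))
        out, n = categorize([r])
        assert out[0].category == "refinery" and n == 0

    def test_unmatched_excluded_and_counted(self):
        out, n = categorize([rec(hints=("MYSTERY",))])
        assert out == [] and n == 1

    def test_single_assignment_partition(self):
        records = [
            rec("A", hints=("WELL",)),
            rec("B", hints=("PORT", "TRI")),
            rec("C", hints=("NPL",)),
        ]
        out, _ = categorize(records)
        assert [r.category for r in out] == ["oil_gas_well", "fossil_port_terminal", "cleanup_radioactive"]

    def test_equal_priority_conflict_is_config_error(self):
        book = (
            Rule(1, "refinery", frozenset({"X"})),
            Rule(1, "solid_waste", frozenset({"Y"})),
        )
        with pytest.raises(RulebookError):
            categorize([rec(hints=("X", "Y"))], book)


class TestDedupe:
    def test_similar_addresses_collapse(self):
        a = rec("A", "123 Main St", hints=("TRI",))
        b = rec("B", "123 Main Street", hints=("TRI",))
        (a, b), _ = categorize([a, b])
        assert address_similarity("123 Main St", "123 Main Street") >= 0.8
        kept, flagged = dedupe([a, b])
        assert [r.record_id for r in kept] == ["A"] and flagged == []

    def test_different_categories_both_retained(self):
        a = rec("A", "123 Main St", hints=("NAICS:32411",))
        b = rec("B", "123 Main Street", hints=("PORT",))
        cats, _ = categorize([a, b])
        kept, _ = dedupe(cats)
        assert len(kept) == 2

    def test_dissimilar_addresses_flagged_and_dropped_by_default(self):
        a = rec("A", "1 Ocean Rd", hints=("TRI",))
        b = rec("B", "987 Mountain Ave", hints=("TRI",))
        cats, _ = categorize([a, b])
        assert address_similarity("1 Ocean Rd", "987 Mountain Ave") < 0.8
        kept, flagged = dedupe(cats)
        assert kept == [] and len(flagged) == 2

    def test_plausibility_predicate_can_rescue(self):
        a = rec("A", "1 Ocean Rd", hints=("TRI",))
        b = rec("B", "987 Mountain Ave", hints=("TRI",))
        cats, _ = categorize([a, b])
        kept, _ = dedupe(cats, implausible=lambda r: False)
        assert len(kept) == 2

    def test_idempotent(self):
        records = [
            rec("A", "123 Main St", hints=("TRI",)),
            rec("B", "123 MAIN STREET", hints=("TRI",)),
            rec("C", "5 Bay Rd", x=500.0, hints=("TRI",)),
        ]
        cats, _ = categorize(records)
        once, _ = dedupe(cats)
        twice, _ = dedupe(once)
        assert once == twice


class TestFootprints:
    def test_point_in_parcel_uses_parcel(self):
        parcel = box(0, 0, 200, 200)
        r = rec("A", x=100, y=100, hints=("TRI",))
        cats, _ = categorize([r])
        sites = assign_footprint(cats, [parcel])
        assert sites[0].footprint.equals(parcel)
        assert sites[0].provenance == "parcel"

    def test_buffer_radius_algebra(self):
        # median area pi m^2 -> radius exactly 1 m
        r = rec("A", x=1e6, y=1e6, hints=("TRI",))
        cats, _ = categorize([r])
        sites = assign_footprint(cats, [], {"tri_industrial": math.pi})
        assert sites[0].provenance == "buffer"
        assert sites[0].footprint.bounds[2] - 1e6 == pytest.approx(1.0, rel=1e-3)
        assert sites[0].footprint.area == pytest.approx(math.pi, rel=1e-3)

    def test_wells_stay_points(self):
        cats, _ = categorize([rec("W", hints=("WELL",))])
        sites = assign_footprint(cats, [box(0, 0, 200, 200)])
        assert isinstance(sites[0].footprint, Point)
        assert sites[0].provenance == "point"

    def test_missing_category_fallback_is_error(self):
        cats, _ = categorize([rec("A", x=1e6, y=1e6, hints=("NPL",))])
        with pytest.raises(ValueError, match="cleanup_radioactive"):
            assign_footprint(cats, [])

    def test_median_from_intersected_parcels_of_same_category(self):
        parcels = [box(0, 0, 100, 100), box(200, 0, 240, 40)]  # areas 1e4, 1600
        inside1 = rec("A", x=50, y=50, hints=("TRI",))
        inside2 = rec("B", x=220, y=20, hints=("TRI",))
        outside = rec("C", x=1e5, y=1e5, hints=("TRI",))
        cats, _ = categorize([inside1, inside2, outside])
        sites = {s.site_id: s for s in assign_footprint(cats, parcels)}
        a_med = np.median([1e4, 1600.0])
        assert sites["C"].footprint.area == pytest.approx(a_med, rel=1e-3)


class TestFudsResolution:
    def test_ratio_arithmetic(self):
        a = box(0, 0, 10, 10)          # area 100
        b = box(6, 0, 16, 10)          # overlap 40 with a
        assert overlap_ratio(a, b) == pytest.approx(0.40)

    def test_small_overlap_split_preserves_area_and_disjointness(self):
        a = box(0, 0, 10, 10)
        b = box(6, 0, 16, 10)          # ratio 0.40 -> split
        resolved, unresolved = resolve_fuds([], [("A", a), ("B", b)])
        assert unresolved == []
        assert len(resolved) == 2
        union_area = a.union(b).area
        assert sum(s.footprint.area for s in resolved) == pytest.approx(union_area)
        inter = resolved[0].footprint.intersection(resolved[1].footprint)
        assert inter.area == pytest.approx(0.0, abs=1e-9)
        # even split: each side of the centroid bisector
        assert resolved[0].footprint.area == pytest.approx(80.0)
        assert resolved[1].footprint.area == pytest.approx(80.0)

    def test_large_overlap_merges(self):
        a = box(0, 0, 10, 10)
        b = box(5, 0, 15, 10)          # overlap 50, ratio 0.50 -> merge
        resolved, unresolved = resolve_fuds([], [("A", a), ("B", b)])
        assert len(resolved) == 1 and unresolved == []
        assert resolved[0].footprint.area == pytest.approx(a.union(b).area)
        assert "merged" in resolved[0].flags

    def test_three_way_overlap_flagged_unresolved(self):
        a = box(0, 0, 10, 10)
        b = box(5, 0, 15, 10)
        c = box(2, 5, 12, 15)
        resolved, unresolved = resolve_fuds([], [("A", a), ("B", b), ("C", c)])
        assert resolved == []
        assert {s.site_id for s in unresolved} == {"A", "B", "C"}
        assert all("unresolved_multiway" in s.flags for s in unresolved)

    def test_points_buffered_to_median_polygon_area_and_clipped(self):
        a = box(0, 0, 10, 10)
        pt_far = rec("P1", x=100, y=100)
        pt_near = rec("P2", x=12, y=5)   # buffer will touch polygon A
        pt_inside = rec("P3", x=5, y=5)  # already represented by A
        resolved, _ = resolve_fuds([pt_far, pt_near, pt_inside], [("A", a)])
        by_id = {s.site_id: s for s in resolved}
        assert set(by_id) == {"A", "P1", "P2"}
        assert by_id["P1"].footprint.area == pytest.approx(100.0, rel=1e-3)
        assert by_id["P2"].footprint.intersection(a).area == pytest.approx(0.0, abs=1e-9)

    def test_resolved_set_zero_pairwise_overlap(self):
        polys = [("A", box(0, 0, 10, 10)), ("B", box(6, 0, 16, 10)), ("C", box(30, 30, 42, 40))]
        pts = [rec("P", x=50, y=5)]
        resolved, _ = resolve_fuds(pts, polys)
        geoms = [s.footprint for s in resolved]
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].intersection(geoms[j]).area == pytest.approx(0.0, abs=1e-9)


class TestCoastAndOffshore:
    land = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])

    def _site(self, geom, sid="S", cat="tri_industrial"):
        return HazardSite(sid, cat, geom, "buffer")

    def test_landward_footprint_unchanged(self):
        s = self._site(box(10, 10, 20, 20))
        out, n = clip_to_coast([s], self.land)
        assert n == 0 and out[0].footprint.equals(box(10, 10, 20, 20))

    def test_straddling_footprint_shrinks(self):
        s = self._site(box(90, 10, 120, 20))
        out, _ = clip_to_coast([s], self.land)
        assert out[0].footprint.area < 300

    def test_fully_seaward_dropped(self):
        s = self._site(box(200, 200, 210, 210))
        out, n = clip_to_coast([s], self.land)
        assert out == [] and n == 1

    def test_offshore_wells_excluded_boundary_inclusive(self):
        bgs = [box(0, 0, 100, 100)]
        inside = HazardSite("W1", "oil_gas_well", Point(50, 50), "point")
        on_edge = HazardSite("W2", "oil_gas_well", Point(100, 50), "point")
        offshore = HazardSite("W3", "oil_gas_well", Point(150, 50), "point")
        kept = exclude_offshore_wells([inside, on_edge, offshore], bgs)
        assert [w.site_id for w in kept] == ["W1", "W2"]


class TestSiteElevation:
    def _dem(self, values):
        return Grid(values=np.asarray(values, dtype=float), xmin=0, ymin=0, cell=10.0)

    def test_quartile_interpolation(self):
        # footprint covering exactly cells {1,2,3,4} m -> q25 = 1.75
        dem = self._dem([[1, 2], [3, 4]])
        site = HazardSite("S", "refinery", box(0, 0, 20, 20), "parcel")
        assert site_elevation(site, dem) == pytest.approx(1.75)

    def test_constant_field(self):
        dem = self._dem(np.full((4, 4), 2.0))
        site = HazardSite("S", "refinery", box(5, 5, 35, 35), "parcel")
        assert site_elevation(site, dem) == pytest.approx(2.0)

    def test_point_site_uses_containing_cell(self):
        dem = self._dem([[1, 2], [3, 4]])
        site = HazardSite("W", "oil_gas_well", Point(15, 15), "point")
        assert site_elevation(site, dem) == 2.0

    def test_no_cells_is_error(self):
        dem = self._dem([[1, 2], [3, 4]])
        tiny = HazardSite("S", "refinery", box(0.1, 0.1, 0.2, 0.2), "parcel")
        with pytest.raises(ValueError, match="S"):
            site_elevation(tiny, dem)
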