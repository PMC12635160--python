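"""Cleaning of raw hazardous-site registry records into analysis-ready sites.

Raw records from facility registries are noisy: imprecise coordinates,
remediated/closed facilities, duplicate entries across programs, and
ad-hoc geometries. This module implements the cleaning pipeline:

1. ``filter_records`` — drop imprecise / remediated / post-2020-end records,
   keeping inactive facilities (residual hazards remain on site).
2. ``categorize`` — assign each record exactly one of eleven mutually
   exclusive hazard categories via a priority-ordered rulebook over
   permit/program codes, industry (NAICS-style) codes, and keywords.
3. ``dedupe`` — collapse records with the same category, identical
   coordinates and fuzzy-similar addresses; cross-category coincidences
   are retained; same-coordinate but dissimilar-address pairs are
   flagged and resolved by a plausibility predicate.
4. ``assign_footprint`` — tax parcel under the point if any, otherwise a
   circular buffer with the category's median intersected-parcel area;
   oil/gas wells stay points (well pads are small).
5. ``resolve_fuds`` — formerly-used-defense-site points and polygons are
   merged into a zero-overlap polygon set using the overlap-ratio rule
   (share of the smaller polygon: <=45% split evenly, >45% merge;
   three-or-more-way overlaps are flagged unresolved).
6. ``clip_to_coast`` / ``exclude_offshore_wells`` — restrict to land.
7. ``site_elevation`` — 25th percentile of DEM cell-center elevations
   within the footprint (flood exposure is controlled by the low
   portion of a site, not its mean elevation).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import NODATA, Grid

CATEGORIES = (
    "power_plant",
    "animal_operation",
    "sewage_treatment",
    "hazardous_waste_tsd",
    "tri_industrial",
    "solid_waste",
    "cleanup_radioactive",
    "refinery",
    "fossil_port_terminal",
    "oil_gas_well",
    "fuds",
)

#: locational accuracy beyond which a record is considered imprecise (m)
MAX_ACCURACY_M = 50.0

#: FUDS overlap-ratio boundary between "split evenly" and "merge"
FUDS_MERGE_RATIO = 0.45


@dataclass
class RawSiteRecord:
    """One uncleaned registry row (point unless a FUDS polygon is attached)."""

    record_id: str
    source: str
    address: str
    x: float
    y: float
    hints: tuple[str, ...] = ()
    active: bool = True
    end_year: int | None = None
    accuracy_m: float | None = None
    zip_level: bool = False      # coordinates derived from zip code only
    remediated: bool = False     # contamination addressed / permanently closed
    geometry: Polygon | None = None  # FUDS polygons only
    category: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"record {self.record_id}: non-finite coordinates")
        if self.accuracy_m is not None and self.accuracy_m < 0:
            raise ValueError(f"record {self.record_id}: negative accuracy")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class HazardSite:
    """A cleaned site ready for flood-risk analysis."""

    site_id: str
    category: str
    footprint: Point | Polygon
    provenance: str  # parcel | buffer | fuds_polygon | fuds_buffer | point
    elevation_q25: float | None = None
    gauge_id: str | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# 1. record filtering
# ---------------------------------------------------------------------------

def filter_records(records: Iterable[RawSiteRecord]) -> list[RawSiteRecord]:
    """Drop imprecise, remediated/closed, and end-dated records.

    Records with locational accuracy worse than 50 m or zip-code-level
    geocoding are removed, as are remediated/closed facilities and
    records whose regulatory end date is 2020 or earlier. Inactive
    facilities and expired permits are deliberately retained: residual
    hazardous material can persist at such sites.
    """
    kept = []
    for r in records:
        if r.accuracy_m is not None and r.accuracy_m > MAX_ACCURACY_M:
            continue
        if r.zip_level:
            continue
        if r.remediated:
            continue
        if r.end_year is not None and r.end_year <= 2020:
            continue
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# 2. categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One rulebook entry: any matching hint assigns ``category``.

    ``priority`` resolves records matching several rules — the lowest
    number wins. Two distinct-category rules at equal priority matching
    one record is a configuration error.
    """

    priority: int
    category: str
    hints: frozenset[str]

    def matches(self, record: RawSiteRecord) -> bool:
        return bool(self.hints.intersection(h.upper() for h in record.hints))


#: default rulebook: program codes, NAICS-style industry prefixes, keywords.
#: Refineries outrank generic TRI/port hints so multi-permit records resolve
#: to the most specific category.
DEFAULT_RULEBOOK: tuple[Rule, ...] = (
    Rule(0, "oil_gas_well", frozenset({"WELL", "NAICS:211"})),
    Rule(0, "fuds", frozenset({"FUDS"})),
    Rule(1, "refinery", frozenset({"NAICS:32411", "REFINERY"})),
    Rule(2, "power_plant", frozenset({"NAICS:2211", "EGRID", "NUCLEAR"})),
    Rule(2, "sewage_treatment", frozenset({"NPDES-POTW", "NAICS:22132"})),
    Rule(2, "animal_operation", frozenset({"CAFO", "NAICS:112"})),
    Rule(2, "hazardous_waste_tsd", frozenset({"RCRA-TSD"})),
    Rule(2, "solid_waste", frozenset({"LANDFILL", "NAICS:5622"})),
    Rule(2, "cleanup_radioactive", frozenset({"NPL", "RADIOACTIVE", "CERCLIS"})),
    Rule(3, "fossil_port_terminal", frozenset({"PORT", "TERMINAL", "NAICS:4247"})),
    Rule(4, "tri_industrial", frozenset({"TRI"})),
)


class RulebookError(ValueError):
    """Ambiguous rulebook configuration (equal-priority conflicting matches)."""


def categorize(
    records: Iterable[RawSiteRecord],
    rulebook: Sequence[Rule] = DEFAULT_RULEBOOK,
) -> tuple[list[RawSiteRecord], int]:
    """Assign exactly one category per record.

    Returns ``(categorized records, n_unmatched)`` where unmatched
    records (no rule fires) are excluded and counted.
    """
    out: list[RawSiteRecord] = []
    n_unmatched = 0
    for r in records:
        matches = [rule for rule in rulebook if rule.matches(r)]
        if not matches:
            n_unmatched += 1
            continue
        best_priority = min(rule.priority for rule in matches)
        best = {rule.category for rule in matches if rule.priority == best_priority}
        if len(best) > 1:
            raise RulebookError(
                f"record {r.record_id}: rules at priority {best_priority} "
                f"match conflicting categories {sorted(best)}"
            )
        out.append(replace(r, category=best.pop()))
    return out, n_unmatched


# ---------------------------------------------------------------------------
# 3. deduplication
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_address(address: str) -> str:
    """Upper-case, strip punctuation, collapse whitespace."""
    s = _PUNCT.sub(" ", address.upper())
    return _WS.sub(" ", s).strip()


def address_similarity(a: str, b: str) -> float:
    """Normalized indel similarity of two normalized addresses.

    ``2 * LCS(a, b) / (len(a) + len(b))`` — 1.0 for identical strings,
    0.0 for disjoint ones. Computed by the standard longest-common-
    subsequence dynamic program (addresses are short).
    """
    a, b = normalize_address(a), normalize_address(b)
    if not a and not b:
        return 1.0
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0
    prev = np.zeros(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        cur = np.zeros(m + 1, dtype=np.int32)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    lcs = int(prev[m])
    return 2.0 * lcs / (n + m)


def dedupe(
    records: Sequence[RawSiteRecord],
    similarity_threshold: float = 0.8,
    implausible: Callable[[RawSiteRecord], bool] | None = None,
) -> tuple[list[RawSiteRecord], list[RawSiteRecord]]:
    """Collapse duplicate records; returns ``(kept, flagged)``.

    Duplicates are records with the same category, identical coordinates
    and address similarity at or above the threshold; the first record
    (by input order) represents the group. Identical coordinates with
    different categories are distinct facilities and both retained.
    Same-coordinate, same-category pairs with *dissimilar* addresses are
    flagged for plausibility review; the ``implausible`` predicate
    decides which flagged records to drop (default: drop all flagged —
    coordinate collisions of unrelated addresses usually indicate a
    geocoding failure).
    """
    if implausible is None:
        implausible = lambda r: True  # noqa: E731

    groups: dict[tuple[str, float, float], list[RawSiteRecord]] = {}
    order: list[tuple[str, float, float]] = []
    for r in records:
        if r.category is None:
            raise ValueError(f"record {r.record_id} not categorized")
        key = (r.category, r.x, r.y)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    kept: list[RawSiteRecord] = []
    flagged: list[RawSiteRecord] = []
    for key in order:
        bucket = groups[key]
        clusters: list[list[RawSiteRecord]] = []
        for r in bucket:
            home = None
            for cl in clusters:
                if address_similarity(r.address, cl[0].address) >= similarity_threshold:
                    home = cl
                    break
            if home is None:
                clusters.append([r])
            else:
                home.append(r)
        if len(clusters) == 1:
            kept.append(clusters[0][0])
        else:
            # same coords + category but dissimilar addresses: review
            for cl in clusters:
                rep = cl[0]
                flagged.append(rep)
                if not implausible(rep):
                    kept.append(rep)
    return kept, flagged


# ---------------------------------------------------------------------------
# 4. footprint assignment
# ---------------------------------------------------------------------------

def assign_footprint(
    records: Sequence[RawSiteRecord],
    parcels: Sequence[Polygon],
    fallback_median_areas: Mapping[str, float] | None = None,
) -> list[HazardSite]:
    """Attach a polygon footprint to every non-well, non-FUDS record.

    A record whose point lies inside a tax parcel takes that parcel.
    Remaining records get a circular buffer whose area equals the median
    intersected-parcel area of their category (``r = sqrt(A_med / pi)``);
    a category with no parcel hits must supply a fallback area. Wells
    keep their point geometry.
    """
    fallback_median_areas = fallback_median_areas or {}
    tree = STRtree(list(parcels)) if parcels else None

    hits: dict[str, Polygon] = {}
    areas_by_cat: dict[str, list[float]] = {}
    for r in records:
        if r.category in ("oil_gas_well", "fuds"):
            continue
        parcel = None
        if tree is not None:
            for idx in tree.query(r.point, predicate="covered_by"):
                parcel = parcels[int(idx)]
                break
        if parcel is not None:
            hits[r.record_id] = parcel
            areas_by_cat.setdefault(r.category, []).append(parcel.area)

    out: list[HazardSite] = []
    for r in records:
        if r.category == "oil_gas_well":
            out.append(HazardSite(r.record_id, r.category, r.point, "point"))
            continue
        if r.category == "fuds":
            continue  # handled by resolve_fuds
        if r.record_id in hits:
            out.append(HazardSite(r.record_id, r.category, hits[r.record_id], "parcel"))
        else:
            if r.category in areas_by_cat:
                a_med = float(np.median(areas_by_cat[r.category]))
            elif r.category in fallback_median_areas:
                a_med = float(fallback_median_areas[r.category])
            else:
                raise ValueError(
                    f"category {r.category!r} has no parcel-intersecting records "
                    "and no fallback median area was configured"
                )
            radius = math.sqrt(a_med / math.pi)
            out.append(HazardSite(r.record_id, r.category, r.point.buffer(radius, quad_segs=64), "buffer"))
    return out


# ---------------------------------------------------------------------------
# 5. FUDS resolution
# ---------------------------------------------------------------------------

def _halfplane(center_a: Point, center_b: Point, extent: float = 1e7) -> Polygon:
    """Large polygon covering the halfplane of points nearer ``center_a``.

    Bounded by the perpendicular bisector of the two centroids.
    """
    ax, ay, bx, by = center_a.x, center_a.y, center_b.x, center_b.y
    mx, my = (ax + bx) / 2.0, (ay + by) / 2.0
    dx, dy = bx - ax, by - ay
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("coincident centroids: bisector undefined")
    ux, uy = dx / norm, dy / norm      # unit vector a -> b
    px, py = -uy, ux                   # along the bisector
    # rectangle on a's side of the bisector
    corners = [
        (mx + px * extent, my + py * extent),
        (mx - px * extent, my - py * extent),
        (mx - px * extent - ux * extent, my - py * extent - uy * extent),
        (mx + px * extent - ux * extent, my + py * extent - uy * extent),
    ]
    return Polygon(corners)


def overlap_ratio(a: Polygon, b: Polygon) -> float:
    """Area of the overlap divided by the area of the smaller polygon."""
    inter = a.intersection(b).area
    smaller = min(a.area, b.area)
    if smaller == 0:
        return 0.0
    return inter / smaller


def resolve_fuds(
    points: Sequence[RawSiteRecord],
    polygons: Sequence[tuple[str, Polygon]],
) -> tuple[list[HazardSite], list[HazardSite]]:
    """Build a zero-overlap FUDS footprint set; returns (resolved, unresolved).

    Polygons are primary. Points falling outside every polygon get a
    circular buffer with the median polygon area, clipped by any polygon
    they touch. Two-polygon overlaps are split evenly along the
    perpendicular bisector of the centroids when the overlap ratio
    (overlap area / smaller polygon area) is at most 45%, merged into one
    site above that. Connected components of three or more mutually
    overlapping polygons are emitted unresolved with a flag.
    """
    polys = [(sid, geom) for sid, geom in polygons]
    n = len(polys)

    # overlap graph among polygons
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if polys[i][1].intersection(polys[j][1]).area > 0:
                adj[i].add(j)
                adj[j].add(i)

    # connected components
    seen: set[int] = set()
    components: list[list[int]] = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        components.append(sorted(comp))

    resolved: list[HazardSite] = []
    unresolved: list[HazardSite] = []
    resolved_geoms: list[Polygon] = []

    def _emit(site_id: str, geom: Polygon, provenance: str, flags=()) -> None:
        resolved.append(HazardSite(site_id, "fuds", geom, provenance, flags=tuple(flags)))
        resolved_geoms.append(geom)

    for comp in components:
        if len(comp) == 1:
            sid, geom = polys[comp[0]]
            _emit(sid, geom, "fuds_polygon")
        elif len(comp) == 2:
            (sid_a, a), (sid_b, b) = polys[comp[0]], polys[comp[1]]
            ratio = overlap_ratio(a, b)
            if ratio > FUDS_MERGE_RATIO:
                _emit(f"{sid_a}+{sid_b}", a.union(b), "fuds_polygon", ["merged"])
            else:
                overlap = a.intersection(b)
                half_a = _halfplane(a.centroid, b.centroid)
                piece_a = overlap.intersection(half_a)
                piece_b = overlap.difference(half_a)
                new_a = a.difference(overlap).union(piece_a)
                new_b = b.difference(overlap).union(piece_b)
                _emit(sid_a, new_a, "fuds_polygon", ["split"])
                _emit(sid_b, new_b, "fuds_polygon", ["split"])
        else:
            # >=3 mutually overlapping facilities: needs manual review
            for k in comp:
                sid, geom = polys[k]
                unresolved.append(
                    HazardSite(sid, "fuds", geom, "fuds_polygon", flags=("unresolved_multiway",))
                )

    if polys:
        median_area = float(np.median([g.area for _, g in polys]))
    else:
        median_area = float("nan")

    poly_union = unary_union([g for _, g in polys]) if polys else None
    for r in points:
        pt = r.point
        if poly_union is not None and poly_union.covers(pt):
            continue  # already represented by a polygon facility
        if not polys:
            raise ValueError(
                "FUDS points without any polygons: no median area to buffer with"
            )
        radius = math.sqrt(median_area / math.pi)
        buf = pt.buffer(radius, quad_segs=64)
        if poly_union is not None:
            buf = buf.difference(poly_union)
        # buffered points may also collide with each other; earlier wins
        for g in resolved_geoms:
            if buf.intersects(g):
                buf = buf.difference(g)
        if buf.is_empty:
            continue
        _emit(r.record_id, buf, "fuds_buffer")

    return resolved, unresolved


# ---------------------------------------------------------------------------
# 6. coastal clipping and offshore exclusion
# ---------------------------------------------------------------------------

def clip_to_coast(
    sites: Sequence[HazardSite], land: Polygon
) -> tuple[list[HazardSite], int]:
    """Intersect footprints with the land polygon; drop emptied sites.

    Returns ``(clipped sites, n_dropped)``.
    """
    out: list[HazardSite] = []
    n_dropped = 0
    for s in sites:
        if isinstance(s.footprint, Point):
            # point (well) geometries are not clipped; offshore wells are
            # handled by the block-group coverage rule instead
            out.append(s)
            continue
        clipped = s.footprint.intersection(land)
        if clipped.is_empty or clipped.area == 0:
            n_dropped += 1
            continue
        out.append(replace(s, footprint=clipped))
    return out, n_dropped


def exclude_offshore_wells(
    wells: Sequence[HazardSite], blockgroups: Sequence[Polygon]
) -> list[HazardSite]:
    """Keep only wells covered by some block-group polygon (boundary inclusive).

    Block-group geographies terminate at the coastline, so wells beyond
    every block group are offshore and excluded.
    """
    bg_union = unary_union(list(blockgroups)) if blockgroups else None
    if bg_union is None:
        return []
    return [w for w in wells if bg_union.covers(w.footprint)]


# ---------------------------------------------------------------------------
# 7. site elevation
# ---------------------------------------------------------------------------

def site_elevation(site: HazardSite, dem: Grid) -> float:
    """25th percentile of DEM cell-center elevations inside the footprint.

    Point sites use the containing cell's value. Linear interpolation
    between order statistics.
    """
    if isinstance(site.footprint, Point):
        val = dem.value_at(site.footprint.x, site.footprint.y)
        if val == NODATA:
            raise ValueError(f"site {site.site_id}: containing DEM cell is nodata")
        return float(val)

    minx, miny, maxx, maxy = site.footprint.bounds
    xs, ys = dem.cell_centers()
    sel = (xs >= minx - dem.cell) & (xs <= maxx + dem.cell) & (ys >= miny - dem.cell) & (ys <= maxy + dem.cell)
    if not sel.any():
        raise ValueError(f"site {site.site_id}: footprint covers no DEM cells")
    import shapely

    cand_x, cand_y = xs[sel], ys[sel]
    pts = shapely.points(cand_x, cand_y)
    inside = shapely.covers(site.footprint, pts)
    vals = dem.values[sel][inside]
    vals = vals[vals != NODATA]
    if vals.size == 0:
        raise ValueError(
            f"site {site.site_id}: footprint covers no valid-elevation DEM cells"
        )
    return float(np.percentile(vals, 25, method="linear"))


def assign_gauges(sites: Sequence[HazardSite], gauges) -> list[HazardSite]:
    """Attach the Euclidean-nearest tide gauge to each site (by footprint centroid)."""
    gx = np.array([g.x for g in gauges])
    gy = np.array([g.y for g in gauges])
    ids = [g.gauge_id for g in gauges]
    out = []
    for s in sites:
        c = s.footprint.centroid
        k = int(np.argmin((gx - c.x) ** 2 + (gy - c.y) ** 2))
        out.append(replace(s, gauge_id=ids[k]))
    return out
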