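"""Neighborhood exposure outcomes: who lives near at-risk sites.

The analysis universe is restricted twice. First, only counties with at
least one site at risk under the high-emissions scenario by 2100 are
kept (inland counties contribute nothing to coastal flood equity).
Second, only "coastal" block groups — those within 3 km Euclidean
distance of the 10-m elevation line above MHHW — enter the statistical
universe.

Block-group outcomes are dasymetric: a block group is exposed when a
*populated* 30-m cell of it lies within the radius of an at-risk site's
footprint, so large rural block groups are not marked exposed by empty
land. Outcomes per block group, radius, scenario and year:

* ``exposed``  — any at-risk site within the radius of populated cells;
* ``n_sites``  — the number of such sites (each counted once);
* ``eae``      — expected annual exposure, the sum of those sites'
  annual flood probabilities: the expected number of nearby sites
  flooded at least once in the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import NODATA, Grid

RADII_M = (1000.0, 3000.0)
COASTAL_CONTOUR_M = 10.0
COASTAL_BUFFER_M = 3000.0


@dataclass
class BlockGroup:
    """Census-style neighborhood polygon with demographics."""

    bg_id: str
    county_id: str
    geometry: Polygon
    population: float
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def density_km2(self) -> float:
        """Population density in people per square kilometer."""
        area = self.geometry.area
        if area <= 0:
            raise ValueError(f"block group {self.bg_id}: non-positive area")
        return self.population / (area / 1e6)


def site_counties(
    site_footprints: Mapping[str, shapely.Geometry],
    counties: Mapping[str, Polygon],
) -> dict[str, str | None]:
    """County containing each site's footprint centroid (None if outside all)."""
    ids = list(counties)
    geoms = [counties[i] for i in ids]
    tree = STRtree(geoms)
    out: dict[str, str | None] = {}
    for sid, fp in site_footprints.items():
        c = fp.centroid
        hit = tree.query(c, predicate="covered_by")
        out[sid] = ids[int(hit[0])] if len(hit) else None
    return out


def select_study_counties(
    counties: Mapping[str, Polygon],
    site_footprints: Mapping[str, shapely.Geometry],
    risk_table: pd.DataFrame,
) -> set[str]:
    """Counties with at least one at-risk site (RCP 8.5 / 2100 risk table)."""
    at_risk_ids = set(risk_table.loc[risk_table["at_risk"], "site_id"])
    if not at_risk_ids:
        return set()
    county_of = site_counties(
        {s: g for s, g in site_footprints.items() if s in at_risk_ids}, counties
    )
    return {c for c in county_of.values() if c is not None}


def low_elevation_zone(dem: Grid, contour_m: float = COASTAL_CONTOUR_M):
    """Union polygon of valid land DEM cells below ``contour_m`` (m MHHW)."""
    valid = dem.mask_valid() & (dem.values >= 0.0) & (dem.values < contour_m)
    if not valid.any():
        raise ValueError(f"DEM has no land cell below {contour_m} m: no coastal zone")
    rows, cols = np.nonzero(valid)
    half = dem.cell
    x0 = dem.xmin + cols * half
    y1 = dem.ymax - rows * half
    boxes = [box(x, y - half, x + half, y) for x, y in zip(x0, y1)]
    return unary_union(boxes)


def select_coastal_blockgroups(
    blockgroups: Sequence[BlockGroup],
    dem: Grid,
    study_counties: set[str],
    contour_m: float = COASTAL_CONTOUR_M,
    buffer_m: float = COASTAL_BUFFER_M,
) -> list[BlockGroup]:
    """Block groups in study counties within ``buffer_m`` of the contour line.

    The elevation line is the polygonized boundary of the sub-``contour_m``
    land region; the coastal band is its exact Euclidean buffer.
    """
    zone = low_elevation_zone(dem, contour_m)
    band = zone.boundary.buffer(buffer_m)
    return [
        bg
        for bg in blockgroups
        if bg.county_id in study_counties and bg.geometry.intersects(band)
    ]


def populated_cells(
    blockgroup: BlockGroup, popgrid: Grid | None
) -> np.ndarray | Polygon:
    """Centers of populated (pop > 0) grid cells inside the block group.

    Returns an (n, 2) coordinate array; with no population raster
    available the whole polygon is treated as populated (fallback mode)
    and the polygon itself is returned.
    """
    if popgrid is None:
        return blockgroup.geometry
    xs, ys = popgrid.cell_centers()
    pop = popgrid.values
    minx, miny, maxx, maxy = blockgroup.geometry.bounds
    sel = (
        (pop > 0)
        & popgrid.mask_valid()
        & (xs >= minx - popgrid.cell)
        & (xs <= maxx + popgrid.cell)
        & (ys >= miny - popgrid.cell)
        & (ys <= maxy + popgrid.cell)
    )
    if not sel.any():
        return np.empty((0, 2))
    cx, cy = xs[sel], ys[sel]
    pts = shapely.points(cx, cy)
    inside = shapely.covers(blockgroup.geometry, pts)
    return np.column_stack([cx[inside], cy[inside]])


def blockgroup_exposure(
    blockgroup: BlockGroup,
    at_risk_sites: Sequence[tuple[str, shapely.Geometry, float]],
    radius_m: float,
    popgrid: Grid | None = None,
) -> dict:
    """One exposure record: (bg_id, exposed, n_sites, eae) at the radius.

    ``at_risk_sites`` is a sequence of ``(site_id, footprint, p_annual)``.
    Distance runs from populated cell centers (or the polygon in
    fallback mode) to the nearest point of the site footprint; a site
    counts once per block group regardless of how many cells are near it.
    """
    cells = populated_cells(blockgroup, popgrid)
    n_sites = 0
    eae = 0.0
    if isinstance(cells, np.ndarray):
        if len(cells):
            pts = shapely.points(cells[:, 0], cells[:, 1])
            for sid, fp, p in at_risk_sites:
                # bbox prefilter before exact distances
                minx, miny, maxx, maxy = fp.bounds
                near = (
                    (cells[:, 0] >= minx - radius_m)
                    & (cells[:, 0] <= maxx + radius_m)
                    & (cells[:, 1] >= miny - radius_m)
                    & (cells[:, 1] <= maxy + radius_m)
                )
                if not near.any():
                    continue
                d = shapely.distance(pts[near], fp)
                if float(d.min()) <= radius_m:
                    n_sites += 1
                    eae += p
    else:
        for sid, fp, p in at_risk_sites:
            if cells.distance(fp) <= radius_m:
                n_sites += 1
                eae += p
    return {
        "bg_id": blockgroup.bg_id,
        "county_id": blockgroup.county_id,
        "radius_m": radius_m,
        "exposed": n_sites >= 1,
        "n_sites": n_sites,
        "eae": eae,
    }


def exposure_table(
    blockgroups: Sequence[BlockGroup],
    risk_table: pd.DataFrame,
    site_footprints: Mapping[str, shapely.Geometry],
    radii_m: Iterable[float] = RADII_M,
    popgrid: Grid | None = None,
) -> pd.DataFrame:
    """Exposure records for every block group x radius, one scenario/year.

    ``risk_table`` must come from a single scenario and year; only its
    at-risk rows contribute.
    """
    scen = risk_table["scenario"].unique()
    yr = risk_table["year"].unique()
    if len(scen) != 1 or len(yr) != 1:
        raise ValueError("risk_table must hold exactly one scenario and year")
    at_risk = [
        (row.site_id, site_footprints[row.site_id], row.p_annual)
        for row in risk_table.itertuples()
        if row.at_risk
    ]
    rows = []
    for radius in radii_m:
        for bg in blockgroups:
            rec = blockgroup_exposure(bg, at_risk, radius, popgrid)
            rec["scenario"] = scen[0]
            rec["year"] = int(yr[0])
            rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "bg_id",
            "county_id",
            "scenario",
            "year",
            "radius_m",
            "exposed",
            "n_sites",
            "eae",
        ],
    )
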