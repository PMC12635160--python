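"""Fixture-bundle serialization: GeoJSON vectors, ASCII-grid rasters, CSV tables.

A bundle directory is self-describing: ``manifest.json`` lists every
layer, the generator seed, and the planar metric CRS tag. A bundle
written from a :class:`~coastrisk.synth.SyntheticRegion` and read back
reproduces the region's geometries and tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .flood import FloodReturnCurve, SLRProjection
from .grid import Grid
from .ingest import RawSiteRecord

CRS_TAG = "synthetic-planar-meters"


def feature_collection(geoms, properties) -> dict:
    return {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": CRS_TAG}},
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, properties)
        ],
    }


def write_geojson(path: Path, geoms, properties) -> None:
    path.write_text(json.dumps(feature_collection(geoms, properties)))


def read_geojson(path: Path):
    fc = json.loads(path.read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f["properties"] for f in fc["features"]]
    return geoms, props


def write_fixture_bundle(region, directory) -> dict:
    """Write all region layers to ``directory``; returns the manifest."""
    from .synth import SyntheticRegion  # noqa: F401 — documented input type

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layers: dict[str, str] = {}

    def _reg(name: str, filename: str) -> Path:
        layers[name] = filename
        return directory / filename

    region.dem.write_ascii(_reg("dem", "dem.asc"))
    if region.popgrid is not None:
        region.popgrid.write_ascii(_reg("popgrid", "popgrid.asc"))

    write_geojson(
        _reg("coastline", "coastline.geojson"), [region.coastline], [{"name": "coastline"}]
    )
    write_geojson(_reg("land", "land.geojson"), [region.land], [{"name": "land"}])
    write_geojson(
        _reg("counties", "counties.geojson"),
        list(region.counties.values()),
        [{"county_id": cid} for cid in region.counties],
    )
    write_geojson(
        _reg("blockgroups", "blockgroups.geojson"),
        [bg.geometry for bg in region.blockgroups],
        [
            {
                "bg_id": bg.bg_id,
                "county_id": bg.county_id,
                "population": bg.population,
                **bg.covariates,
            }
            for bg in region.blockgroups
        ],
    )
    write_geojson(
        _reg("parcels", "parcels.geojson"),
        region.parcels,
        [{"parcel_id": i} for i in range(len(region.parcels))],
    )
    write_geojson(
        _reg("fuds_polygons", "fuds_polygons.geojson"),
        [g for _, g in region.fuds_polygons],
        [{"record_id": sid} for sid, _ in region.fuds_polygons],
    )

    sites = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "source": r.source,
                "address": r.address,
                "x": r.x,
                "y": r.y,
                "hints": "|".join(r.hints),
                "active": r.active,
                "end_year": r.end_year,
                "accuracy_m": r.accuracy_m,
                "zip_level": r.zip_level,
                "remediated": r.remediated,
            }
            for r in region.raw_sites
        ]
    )
    sites.to_csv(_reg("raw_sites", "raw_sites.csv"), index=False, float_format="%.17g")

    gauges = pd.DataFrame(
        [
            {
                "gauge_id": g.gauge_id,
                "x": g.x,
                "y": g.y,
                "lambda_rate": g.lambda_rate,
                "threshold_mu": g.threshold_mu,
                "scale_sigma": g.scale_sigma,
                "shape_xi": g.shape_xi,
                "cap_rate": g.cap_rate,
            }
            for g in region.gauges
        ]
    )
    gauges.to_csv(_reg("gauges", "gauges.csv"), index=False, float_format="%.17g")

    slr_rows = []
    for p in region.slr:
        for i, v in enumerate(p.samples):
            slr_rows.append(
                {
                    "gauge_id": p.gauge_id,
                    "scenario": p.scenario,
                    "year": p.year,
                    "sample_index": i,
                    "value_m": v,
                }
            )
    pd.DataFrame(slr_rows).to_csv(_reg("slr", "slr_samples.csv"), index=False, float_format="%.17g")

    manifest = {
        "seed": region.config.seed,
        "crs": CRS_TAG,
        "cell_m": region.config.cell_m,
        "layers": layers,
        "popgrid_fallback": region.popgrid is None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_fixture_bundle(directory):
    """Read a bundle back into the layer objects the pipeline consumes.

    Returns a dict with keys matching the manifest layers plus parsed
    domain objects (gauges as return curves, slr as projections, raw
    sites as records).
    """
    from .exposure import BlockGroup

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = manifest["layers"]
    out: dict = {"manifest": manifest}

    out["dem"] = Grid.read_ascii(directory / layers["dem"])
    out["popgrid"] = (
        Grid.read_ascii(directory / layers["popgrid"]) if "popgrid" in layers else None
    )
    (coast_geom,), _ = read_geojson(directory / layers["coastline"])
    out["coastline"] = coast_geom
    (land_geom,), _ = read_geojson(directory / layers["land"])
    out["land"] = land_geom
    geoms, props = read_geojson(directory / layers["counties"])
    out["counties"] = {p["county_id"]: g for g, p in zip(geoms, props)}
    geoms, props = read_geojson(directory / layers["blockgroups"])
    out["blockgroups"] = [
        BlockGroup(
            bg_id=p.pop("bg_id"),
            county_id=p.pop("county_id"),
            geometry=g,
            population=p.pop("population"),
            covariates=dict(p),
        )
        for g, p in zip(geoms, props)
    ]
    geoms, _ = read_geojson(directory / layers["parcels"])
    out["parcels"] = geoms
    geoms, props = read_geojson(directory / layers["fuds_polygons"])
    out["fuds_polygons"] = [(p["record_id"], g) for g, p in zip(geoms, props)]

    sites = pd.read_csv(directory / layers["raw_sites"], float_precision="round_trip")
    out["raw_sites"] = [
        RawSiteRecord(
            record_id=row.record_id,
            source=row.source,
            address=row.address,
            x=row.x,
            y=row.y,
            hints=tuple(str(row.hints).split("|")) if pd.notna(row.hints) else (),
            active=bool(row.active),
            end_year=None if pd.isna(row.end_year) else int(row.end_year),
            accuracy_m=None if pd.isna(row.accuracy_m) else float(row.accuracy_m),
            zip_level=bool(row.zip_level),
            remediated=bool(row.remediated),
        )
        for row in sites.itertuples()
    ]

    gauges = pd.read_csv(directory / layers["gauges"], float_precision="round_trip")
    out["gauges"] = [
        FloodReturnCurve(
            gauge_id=row.gauge_id,
            lambda_rate=row.lambda_rate,
            threshold_mu=row.threshold_mu,
            scale_sigma=row.scale_sigma,
            shape_xi=row.shape_xi,
            cap_rate=row.cap_rate,
            x=row.x,
            y=row.y,
        )
        for row in gauges.itertuples()
    ]

    slr = pd.read_csv(directory / layers["slr"], float_precision="round_trip")
    out["slr"] = [
        SLRProjection(
            gauge_id=gid,
            scenario=scen,
            year=int(yr),
            samples=grp.sort_values("sample_index")["value_m"].to_numpy(),
        )
        for (gid, scen, yr), grp in slr.groupby(["gauge_id", "scenario", "year"])
    ]
    return out
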