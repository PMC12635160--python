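"""End-to-end orchestration: ingest → flood risk → exposure → equity → report.

``run_pipeline`` drives the whole analysis on a synthetic region (or a
fixture bundle directory) and writes every stage's table plus a run
manifest recording seeds, row counts and exclusion-rule tallies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import equity, exposure, flood, ingest, report
from .io import read_fixture_bundle, write_geojson
from .synth import SCENARIOS, YEARS, RegionConfig, SyntheticRegion, make_region, make_sites_and_demographics

def ingest_sites(
    raw_records,
    parcels,
    fuds_polygons,
    land,
    blockgroup_polys,
    dem,
    gauges,
    rulebook=ingest.DEFAULT_RULEBOOK,
    log: dict | None = None,
):
    """Full cleaning pipeline; returns analysis-ready HazardSite list."""
    log = log if log is not None else {}
    n0 = len(raw_records)
    records = ingest.filter_records(raw_records)
    log["n_raw"] = n0
    log["n_dropped_filter"] = n0 - len(records)

    records, n_unmatched = ingest.categorize(records, rulebook)
    log["n_unmatched_category"] = n_unmatched

    records, flagged = ingest.dedupe(records)
    log["n_flagged_dedupe"] = len(flagged)
    log["n_after_dedupe"] = len(records)

    wells = [r for r in records if r.category == "oil_gas_well"]
    fuds_records = [r for r in records if r.category == "fuds"]
    others = [r for r in records if r.category not in ("oil_gas_well", "fuds")]

    # fallback: categories whose records all miss parcels buffer with the
    # overall median parcel area
    fallback = None
    if parcels:
        med = float(np.median([p.area for p in parcels]))
        fallback = {c: med for c in ingest.CATEGORIES}
    sites = ingest.assign_footprint(others + wells, parcels, fallback)

    fuds_ids = {r.record_id for r in fuds_records}
    fuds_points = [r for r in fuds_records if not any(sid == r.record_id for sid, _ in fuds_polygons)]
    fuds_polys = [(sid, g) for sid, g in fuds_polygons if sid in fuds_ids]
    if fuds_polys or fuds_points:
        resolved, unresolved = ingest.resolve_fuds(fuds_points, fuds_polys)
        log["n_fuds_unresolved"] = len(unresolved)
        sites.extend(resolved)

    sites, n_clipped = ingest.clip_to_coast(sites, land)
    log["n_dropped_coast_clip"] = n_clipped

    well_sites = [s for s in sites if s.category == "oil_gas_well"]
    other_sites = [s for s in sites if s.category != "oil_gas_well"]
    kept_wells = ingest.exclude_offshore_wells(well_sites, blockgroup_polys)
    log["n_offshore_wells_excluded"] = len(well_sites) - len(kept_wells)
    sites = other_sites + kept_wells

    out = []
    for s in sites:
        try:
            elev = ingest.site_elevation(s, dem)
        except ValueError:
            log["n_no_elevation"] = log.get("n_no_elevation", 0) + 1
            continue
        s.elevation_q25 = elev
        out.append(s)
    out = ingest.assign_gauges(out, gauges)
    log["n_final_sites"] = len(out)
    return out


def run_pipeline(
    config: RegionConfig | None = None,
    out_dir: str | Path = "results/pipeline",
    bundle_dir: str | Path | None = None,
    region: SyntheticRegion | None = None,
    n_boot: int = 200,
    equity_scenario: tuple[str, int] = ("RCP85", 2100),
) -> dict:
    """Run the full analysis; returns the run manifest (also written to disk).

    Input is one of: a ``RegionConfig`` (a synthetic region is
    generated), a prebuilt region, or a fixture bundle directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {}

    if region is None and bundle_dir is not None:
        bundle = read_fixture_bundle(bundle_dir)
        dem, popgrid = bundle["dem"], bundle["popgrid"]
        land, counties = bundle["land"], bundle["counties"]
        blockgroups = bundle["blockgroups"]
        raw_sites, parcels = bundle["raw_sites"], bundle["parcels"]
        fuds_polygons = bundle["fuds_polygons"]
        gauges, slr = bundle["gauges"], bundle["slr"]
        seed = bundle["manifest"]["seed"]
    else:
        if region is None:
            if config is None:
                raise ValueError("need a config, region, or bundle directory")
            region = make_sites_and_demographics(make_region(config))
        dem, popgrid = region.dem, region.popgrid
        land, counties = region.land, region.counties
        blockgroups = region.blockgroups
        raw_sites, parcels = region.raw_sites, region.parcels
        fuds_polygons = region.fuds_polygons
        gauges, slr = region.gauges, region.slr
        seed = region.config.seed

    bg_polys = [bg.geometry for bg in blockgroups]
    sites = ingest_sites(
        raw_sites, parcels, fuds_polygons, land, bg_polys, dem, gauges, log=log
    )
    write_geojson(
        out_dir / "sites.geojson",
        [s.footprint for s in sites],
        [
            {
                "site_id": s.site_id,
                "category": s.category,
                "provenance": s.provenance,
                "elevation_q25": s.elevation_q25,
                "gauge_id": s.gauge_id,
            }
            for s in sites
        ],
    )

    risk_tables: dict[tuple[str, int], pd.DataFrame] = {}
    for scen in SCENARIOS:
        for yr in YEARS:
            tbl = flood.site_risk_table(sites, slr, gauges, scen, yr)
            risk_tables[(scen, yr)] = tbl
            tbl.to_csv(out_dir / f"site_risk_{scen}_{yr}.csv", index=False)

    summary = report.summarize_by_category(risk_tables)
    summary.to_csv(out_dir / "summary_by_category.csv", index=False)

    footprints = {s.site_id: s.footprint for s in sites}
    study = exposure.select_study_counties(
        counties, footprints, risk_tables[("RCP85", 2100)]
    )
    log["n_study_counties"] = len(study)
    coastal = exposure.select_coastal_blockgroups(blockgroups, dem, study)
    log["n_coastal_blockgroups"] = len(coastal)
    log["popgrid_fallback"] = popgrid is None

    expo_frames = []
    for key, tbl in risk_tables.items():
        expo_frames.append(
            exposure.exposure_table(coastal, tbl, footprints, popgrid=popgrid)
        )
    expo = pd.concat(expo_frames, ignore_index=True)
    expo.to_csv(out_dir / "exposure.csv", index=False)

    # --- equity statistics on the primary scenario-year, 1 km radius -----
    scen, yr = equity_scenario
    prim = expo[
        (expo["scenario"] == scen) & (expo["year"] == yr) & (expo["radius_m"] == 1000.0)
    ].set_index("bg_id")
    cov_df = pd.DataFrame(
        {bg.bg_id: bg.covariates for bg in coastal}
    ).T.loc[prim.index]
    density = pd.Series(
        {bg.bg_id: bg.density_km2 for bg in coastal}, name="density"
    ).loc[prim.index]
    density_z = (density - density.mean()) / max(density.std(ddof=0), 1e-12)

    estimates = []
    concentration = []
    if prim["exposed"].any() and (~prim["exposed"]).any():
        cov_z = equity.standardize(cov_df)
        for name in cov_df.columns:
            try:
                est = equity.fit_exposure_model(
                    prim["exposed"].astype(float),
                    cov_z[name],
                    density_z,
                    prim["county_id"],
                    family="logistic",
                )
            except Exception as exc:  # noqa: BLE001 — logged, not fatal per covariate
                log.setdefault("failed_fits", []).append([name, "logistic", str(exc)])
                continue
            estimates.append(
                {
                    "covariate": name,
                    "model": "logistic",
                    "measure": est.measure,
                    "estimate": est.estimate,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_blockgroups": est.n_blockgroups,
                    "n_counties": est.n_counties,
                }
            )
            if len(prim) >= 10 and prim["n_sites"].sum() > 0:
                res = equity.concentration_analysis(
                    cov_df[name].to_numpy(),
                    prim["n_sites"].to_numpy(dtype=float),
                    covariate=name,
                    n_boot=n_boot,
                    seed=seed,
                )
                concentration.append(
                    {
                        "covariate": name,
                        "category": res.category,
                        "metric": res.metric,
                        "index": res.index,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )
    pd.DataFrame(estimates).to_csv(out_dir / "estimates.csv", index=False)
    pd.DataFrame(concentration).to_csv(out_dir / "concentration.csv", index=False)

    manifest = {
        "seed": seed,
        "stages": log,
        "scenario_years": [[s, y] for s in SCENARIOS for y in YEARS],
        "equity_scenario": list(equity_scenario),
        "n_boot": n_boot,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
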