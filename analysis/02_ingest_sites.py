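"""Clean the raw site registry into analysis-ready hazardous sites.

Applies the full ingest chain — precision/remediation filtering,
priority-rulebook categorization, fuzzy-address deduplication, parcel
and median-area-buffer footprints, FUDS overlap resolution, coastline
clipping, offshore-well exclusion, 25th-percentile elevation and
nearest-gauge assignment — and reports every exclusion tally.
"""

import json

from common import BUNDLE, RESULTS
from coastrisk.io import read_fixture_bundle, write_geojson
from coastrisk.pipeline import ingest_sites

bundle = read_fixture_bundle(BUNDLE)
log: dict = {}
sites = ingest_sites(
    bundle["raw_sites"],
    bundle["parcels"],
    bundle["fuds_polygons"],
    bundle["land"],
    [bg.geometry for bg in bundle["blockgroups"]],
    bundle["dem"],
    bundle["gauges"],
    log=log,
)

write_geojson(
    RESULTS / "sites.geojson",
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

print("ingest log:", json.dumps(log, indent=2))
by_prov: dict = {}
for s in sites:
    by_prov[s.provenance] = by_prov.get(s.provenance, 0) + 1
print("footprint provenance:", by_prov)
print(f"{log['n_final_sites']} cleaned sites -> {RESULTS / 'sites.geojson'}")
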