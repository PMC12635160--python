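"""Per-site annual flood probabilities and the category risk table.

For each site × scenario × year, integrates the gauge's Poisson–GPD
return curve over the full SLR sample distribution (law of total
probability), classifies at-risk sites (p >= 0.01), and prints the
category summary with the RCP 8.5 → 4.5 reduction arithmetic.
"""

from common import BUNDLE, RESULTS
from coastrisk import flood, report
from coastrisk.io import read_fixture_bundle, read_geojson


class SiteRow:
    def __init__(self, geom, props):
        self.footprint = geom
        self.site_id = props["site_id"]
        self.category = props["category"]
        self.elevation_q25 = props["elevation_q25"]
        self.gauge_id = props["gauge_id"]


bundle = read_fixture_bundle(BUNDLE)
geoms, props = read_geojson(RESULTS / "sites.geojson")
sites = [SiteRow(g, p) for g, p in zip(geoms, props)]

tables = {}
for scen in ("RCP45", "RCP85"):
    for yr in (2050, 2100):
        tbl = flood.site_risk_table(sites, bundle["slr"], bundle["gauges"], scen, yr)
        tbl.to_csv(RESULTS / f"site_risk_{scen}_{yr}.csv", index=False)
        tables[(scen, yr)] = tbl

summary = report.summarize_by_category(tables)
summary.to_csv(RESULTS / "summary_by_category.csv", index=False)
print(summary.to_string(index=False))

n85 = int(summary.set_index("category").loc["total", "n_at_risk_RCP85_2100"])
n45 = int(summary.set_index("category").loc["total", "n_at_risk_RCP45_2100"])
absolute, pct = report.scenario_difference(n85, n45)
print(f"\nlimiting emissions to RCP4.5 reduces 2100 at-risk sites "
      f"{n85} -> {n45} (reduction of {absolute}, {pct}% of sites)")
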