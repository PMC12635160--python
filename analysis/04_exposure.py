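"""Define the coastal block-group universe and compute exposure outcomes.

Keeps counties with at least one RCP 8.5 / 2100 at-risk site, restricts
to block groups within 3 km of the 10-m elevation line, and computes
the dasymetric outcomes (exposed flag, at-risk site count, expected
annual exposure) at 1 km and 3 km for every scenario × year.
"""

import pandas as pd

from common import BUNDLE, RESULTS
from coastrisk import exposure
from coastrisk.io import read_fixture_bundle, read_geojson

bundle = read_fixture_bundle(BUNDLE)
geoms, props = read_geojson(RESULTS / "sites.geojson")
footprints = {p["site_id"]: g for g, p in zip(geoms, props)}

risk85 = pd.read_csv(RESULTS / "site_risk_RCP85_2100.csv")
study = exposure.select_study_counties(bundle["counties"], footprints, risk85)
coastal = exposure.select_coastal_blockgroups(bundle["blockgroups"], bundle["dem"], study)
print(f"study counties: {sorted(study)} "
      f"({len(bundle['counties']) - len(study)} counties excluded)")
print(f"coastal block groups: {len(coastal)} of {len(bundle['blockgroups'])}")

frames = []
for scen in ("RCP45", "RCP85"):
    for yr in (2050, 2100):
        risk = pd.read_csv(RESULTS / f"site_risk_{scen}_{yr}.csv")
        frames.append(
            exposure.exposure_table(coastal, risk, footprints, popgrid=bundle["popgrid"])
        )
expo = pd.concat(frames, ignore_index=True)
expo.to_csv(RESULTS / "exposure.csv", index=False)

prim = expo[(expo["scenario"] == "RCP85") & (expo["year"] == 2100)]
for radius, grp in prim.groupby("radius_m"):
    print(f"RCP8.5/2100 @ {radius:.0f} m: {int(grp['exposed'].sum())} exposed block groups "
          f"({100 * grp['exposed'].mean():.1f}%), mean EAE among exposed "
          f"{grp.loc[grp['exposed'], 'eae'].mean():.2f}")
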