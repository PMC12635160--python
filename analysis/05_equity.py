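"""Exposure-disparity statistics on the coastal block-group universe.

Compares covariate distributions between exposed and unexposed block
groups (Mann–Whitney), fits county fixed-effects models per covariate
(logistic OR for the exposed flag; negative-binomial IRR and linear EAE
difference among exposed block groups), and computes concentration
indices with bootstrap CIs. Primary outcome: RCP 8.5 / 2100, 1 km.
"""

import pandas as pd

from common import BUNDLE, RESULTS, STUDY_CONFIG
from coastrisk import equity
from coastrisk.io import read_fixture_bundle

bundle = read_fixture_bundle(BUNDLE)
expo = pd.read_csv(RESULTS / "exposure.csv")
prim = expo[
    (expo["scenario"] == "RCP85") & (expo["year"] == 2100) & (expo["radius_m"] == 1000.0)
].set_index("bg_id")

bgs = {bg.bg_id: bg for bg in bundle["blockgroups"]}
coastal = [bgs[b] for b in prim.index]
cov = pd.DataFrame({bg.bg_id: bg.covariates for bg in coastal}).T.loc[prim.index]
density = pd.Series({bg.bg_id: bg.density_km2 for bg in coastal}).loc[prim.index]
density_z = (density - density.mean()) / density.std(ddof=0)

desc = equity.compare_exposed_unexposed(prim["exposed"].reset_index(drop=True), cov.reset_index(drop=True))
desc.to_csv(RESULTS / "descriptives.csv", index=False)
print("covariates with Mann-Whitney p < 0.05:",
      sorted(desc.loc[desc["p_value"] < 0.05, "covariate"]))

cov_z = equity.standardize(cov)
rows, conc_rows = [], []
exposed_mask = prim["exposed"].to_numpy()
for name in cov.columns:
    est = equity.fit_exposure_model(
        prim["exposed"].astype(float), cov_z[name], density_z, prim["county_id"], "logistic"
    )
    rows.append((name, "logistic", est.measure, est.estimate, est.ci_low, est.ci_high))
    if exposed_mask.sum() >= 20:
        sub = prim[prim["exposed"]]
        try:
            nb = equity.fit_exposure_model(
                sub["n_sites"], cov_z.loc[sub.index, name],
                density_z.loc[sub.index], sub["county_id"], "negative_binomial",
            )
            rows.append((name, "negative_binomial", nb.measure, nb.estimate, nb.ci_low, nb.ci_high))
            lin = equity.fit_exposure_model(
                sub["eae"], cov_z.loc[sub.index, name],
                density_z.loc[sub.index], sub["county_id"], "linear",
            )
            rows.append((name, "linear", lin.measure, lin.estimate, lin.ci_low, lin.ci_high))
        except ValueError as exc:
            print(f"  {name}: secondary models skipped ({exc})")
    res = equity.concentration_analysis(
        cov[name].to_numpy(), prim["n_sites"].to_numpy(dtype=float),
        covariate=name, n_boot=1000, seed=STUDY_CONFIG.seed,
    )
    conc_rows.append((name, res.index, res.ci_low, res.ci_high, res.significant))

est_df = pd.DataFrame(rows, columns=["covariate", "model", "measure", "estimate", "ci_low", "ci_high"])
est_df.to_csv(RESULTS / "estimates.csv", index=False)
conc_df = pd.DataFrame(conc_rows, columns=["covariate", "index", "ci_low", "ci_high", "significant"])
conc_df.to_csv(RESULTS / "concentration.csv", index=False)

assoc = STUDY_CONFIG.assoc_covariate
row = est_df[(est_df["covariate"] == assoc) & (est_df["model"] == "logistic")].iloc[0]
print(f"\ngenerative covariate {assoc}: true standardized OR 1.40, "
      f"estimated {row['estimate']:.2f} [{row['ci_low']:.2f}, {row['ci_high']:.2f}]")
print(conc_df.to_string(index=False))
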