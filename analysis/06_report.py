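"""Final report: synthetic-region headline numbers and the published-table
arithmetic the reporting operations reproduce.

The published national counts are fixed inputs here; the percentages,
scenario reduction and category shares are recomputed by the same
operations used on the synthetic region.
"""

import pandas as pd

from common import RESULTS
from coastrisk import report

summary = pd.read_csv(RESULTS / "summary_by_category.csv").set_index("category")
print("=== synthetic region ===")
print(summary[["total", "n_at_risk_RCP85_2100", "pct_at_risk_RCP85_2100"]].to_string())

print("\n=== published-table arithmetic (counts are inputs) ===")
print(f"5500 of 47,646 at risk (RCP8.5, 2100): {report.percent_1dp(5500, 47646)}%")
print(f"5138 of 47,646 at risk (RCP4.5, 2100): {report.percent_1dp(5138, 47646)}%")
absolute, pct = report.scenario_difference(5500, 5138)
print(f"emissions mitigation reduction: {absolute} sites ({pct}%)")
print(f"TRI industrial share of at-risk total: {report.share_of_total(1870, 5500)}%")
print(f"fossil fuel infrastructure share: {report.share_of_total(16 + 293 + 1944, 5500)}%")
print(f"power plants at risk (RCP8.5, 2100): {report.percent_1dp(134, 443)}%")
print(f"sewage treatment at risk (RCP8.5, 2100): {report.percent_1dp(564, 2582)}%")
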