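"""Summary tables: at-risk counts and percentages by category and scenario.

Percent formatting matches the conventions of published hazard-count
tables: one decimal place, decimal half-up rounding (564/2582 → 21.8),
and integer rounding for shares of the at-risk total.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

SCENARIO_YEARS = (("RCP45", 2050), ("RCP45", 2100), ("RCP85", 2050), ("RCP85", 2100))


def percent_1dp(count: int, total: int) -> float:
    """100·count/total rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def share_of_total(category_count: int, total_at_risk: int) -> int:
    """Integer percent (half-up) of the at-risk total in one category."""
    if total_at_risk <= 0:
        raise ValueError("total at-risk count must be positive")
    frac = Decimal(100) * Decimal(category_count) / Decimal(total_at_risk)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def scenario_difference(count_a: int, count_b: int) -> tuple[int, int]:
    """(absolute reduction, integer percent of the larger count).

    For comparing at-risk totals between two emissions scenarios:
    ``count_a`` is the larger-scenario count, ``count_b`` the smaller.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    absolute = count_a - count_b
    denom = max(count_a, count_b)
    if denom == 0:
        return 0, 0
    pct = int(
        (Decimal(100) * Decimal(abs(absolute)) / Decimal(denom)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    return absolute, pct


def summarize_by_category(risk_tables: Mapping[tuple[str, int], pd.DataFrame]) -> pd.DataFrame:
    """Category × scenario-year at-risk counts and percents, plus a total row.

    ``risk_tables`` maps (scenario, year) → per-site risk DataFrame; all
    four scenario-year combinations are required and must cover the same
    site set with one category per site.
    """
    missing = [k for k in SCENARIO_YEARS if k not in risk_tables]
    if missing:
        raise ValueError(f"missing risk tables for {missing}")

    ref = risk_tables[SCENARIO_YEARS[0]]
    cat_of = ref.set_index("site_id")["category"]
    for key, tbl in risk_tables.items():
        other = tbl.set_index("site_id")["category"]
        if not cat_of.sort_index().equals(other.sort_index()):
            raise ValueError(
                f"risk table {key} disagrees on the site/category partition"
            )

    categories = list(pd.unique(ref["category"]))
    totals = ref.groupby("category").size()

    rows = []
    for cat in categories:
        row: dict = {"category": cat, "total": int(totals[cat])}
        for scen, yr in SCENARIO_YEARS:
            tbl = risk_tables[(scen, yr)]
            n = int(tbl.loc[(tbl["category"] == cat) & tbl["at_risk"]].shape[0])
            row[f"n_at_risk_{scen}_{yr}"] = n
            row[f"pct_at_risk_{scen}_{yr}"] = percent_1dp(n, int(totals[cat]))
        rows.append(row)

    total_row: dict = {"category": "total", "total": int(totals.sum())}
    for scen, yr in SCENARIO_YEARS:
        n = sum(r[f"n_at_risk_{scen}_{yr}"] for r in rows)
        n_distinct = int(risk_tables[(scen, yr)]["at_risk"].sum())
        if n != n_distinct:
            raise ValueError("category partition violated: counts do not add up")
        total_row[f"n_at_risk_{scen}_{yr}"] = n
        total_row[f"pct_at_risk_{scen}_{yr}"] = percent_1dp(n, int(totals.sum()))
    rows.append(total_row)
    return pd.DataFrame(rows)
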