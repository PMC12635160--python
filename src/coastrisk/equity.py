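"""Exposure-disparity statistics: group comparisons, fixed-effects
regressions, and concentration curves/indices.

Three complementary views of inequity in who lives near at-risk sites:

* **Descriptive** — medians/quartiles of each neighborhood covariate in
  exposed vs unexposed block groups with a two-sided Mann–Whitney U
  test (covariates are skewed proportions; no normality assumed, no
  multiplicity adjustment).
* **Model-based** — one marginalization covariate at a time, z-scored
  against the full coastal universe, entered into a logistic
  (exposed yes/no → odds ratio per SD), negative-binomial (number of
  nearby at-risk sites → incidence-rate ratio, exposed block groups
  only) or linear (expected annual exposure → mean difference) model
  with population density and county fixed effects; standard errors are
  county-clustered sandwich estimates.
* **Distributional** — concentration curves order block groups by
  *descending* marginalization and cumulate the share of burden
  (site count or EAE); the concentration index C = 1 − 2·(area under
  the curve) is negative when burden concentrates among more
  marginalized block groups, in [−1, 1], with a nonparametric bootstrap
  CI over block groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class EffectEstimate:
    covariate: str
    model: str         # logistic | negative_binomial | linear
    measure: str       # OR | IRR | mean_difference
    estimate: float
    se: float          # county-clustered, on the estimation scale
    ci_low: float
    ci_high: float
    n_blockgroups: int
    n_counties: int
    n_counties_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.measure in ("OR", "IRR") and self.estimate <= 0:
            raise ValueError(f"{self.measure} must be positive")


@dataclass(frozen=True)
class ConcentrationResult:
    covariate: str
    category: str      # site category or "all"
    metric: str        # n_sites | eae
    index: float
    ci_low: float | None
    ci_high: float | None
    curve: np.ndarray  # (k, 2) points from (0,0) to (1,1)

    @property
    def significant(self) -> bool | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return self.ci_low > 0 or self.ci_high < 0


# ---------------------------------------------------------------------------
# descriptive comparison
# ---------------------------------------------------------------------------

def compare_exposed_unexposed(
    exposed: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Median [25th, 75th] by exposure group and Mann–Whitney p per covariate.

    ``exposed`` is a boolean Series aligned with ``covariates`` rows.
    Covariates that are entirely missing are skipped. Constant
    covariates give p = 1 (all ties). No multiple-comparison adjustment
    is applied.
    """
    if exposed.sum() == 0 or (~exposed).sum() == 0:
        raise ValueError("need at least one exposed and one unexposed block group")
    rows = []
    for name in covariates.columns:
        x = covariates.loc[exposed.values, name].dropna()
        y = covariates.loc[~exposed.values, name].dropna()
        if x.empty and y.empty:
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {
                "covariate": name,
                "exposed_median": x.median(),
                "exposed_q25": x.quantile(0.25),
                "exposed_q75": x.quantile(0.75),
                "unexposed_median": y.median(),
                "unexposed_q25": y.quantile(0.25),
                "unexposed_q75": y.quantile(0.75),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(
    covariates: pd.DataFrame, binary: Sequence[str] = ("cejst_disadvantaged",)
) -> pd.DataFrame:
    """Z-score continuous covariates against the full universe.

    The mean and SD come from *all* rows passed in (the coastal
    block-group universe, not just exposed ones). Binary indicator
    columns are left on their natural {0, 1} scale.
    """
    out = covariates.copy()
    for name in covariates.columns:
        if name in binary:
            continue
        col = covariates[name]
        sd = col.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} has zero variance in the universe")
        out[name] = (col - col.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# fixed-effects regression
# ---------------------------------------------------------------------------

def _design(covariate_z, density_z, county_ids):
    counties = pd.Categorical(county_ids)
    dummies = pd.get_dummies(counties, drop_first=True, dtype=float)
    X = pd.DataFrame({"covariate": np.asarray(covariate_z, dtype=float)})
    density_z = np.asarray(density_z, dtype=float)
    if np.ptp(density_z) > 0:  # constant density would be collinear with the intercept
        X["density"] = density_z
    X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_exposure_model(
    outcome,
    covariate_z,
    density,
    county_ids,
    family: str = "logistic",
) -> EffectEstimate:
    """Effect of one standardized covariate on an exposure outcome.

    ``family`` selects the estimator and reporting scale:

    * ``logistic`` — binary exposed flag; OR = exp(beta) per SD.
      Counties whose outcome does not vary are dropped (their fixed
      effect is not identified) with a logged count.
    * ``negative_binomial`` — count of nearby at-risk sites (NB2,
      dispersion by maximum likelihood); IRR = exp(beta).
    * ``linear`` — expected annual exposure; mean difference per SD.

    Standard errors are county-clustered sandwich estimates with the
    usual finite-cluster correction; 95% CIs use the normal quantile on
    the estimation (log for OR/IRR) scale.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "x": np.asarray(covariate_z, dtype=float),
            "density": np.asarray(density, dtype=float),
            "county": np.asarray(county_ids),
        }
    ).reset_index(drop=True)

    n_dropped = 0
    if family == "logistic":
        var_by_county = df.groupby("county")["y"].nunique()
        degenerate = set(var_by_county.index[var_by_county < 2])
        n_dropped = len(degenerate)
        df = df[~df["county"].isin(degenerate)].reset_index(drop=True)

    n_counties = df["county"].nunique()
    if n_counties < 2:
        raise ValueError("county-clustered errors need at least 2 counties")

    X = _design(df["x"], df["density"], df["county"])
    groups = df["county"]
    fit_kw = dict(cov_type="cluster", cov_kwds={"groups": groups})

    if family == "logistic":
        model = sm.Logit(df["y"], X)
        res = model.fit(disp=0, maxiter=200, **fit_kw)
        measure = "OR"
    elif family == "negative_binomial":
        model = sm.NegativeBinomial(df["y"], X)
        # newton/bfgs stall when the ML dispersion sits at its zero boundary
        # (near-Poisson counts); lbfgs handles the bound cleanly
        res = model.fit(disp=0, maxiter=1000, method="lbfgs", **fit_kw)
        measure = "IRR"
    elif family == "linear":
        model = sm.OLS(df["y"], X)
        res = model.fit(**fit_kw)
        measure = "mean_difference"
    else:
        raise ValueError(f"unknown model family {family!r}")

    if not np.isfinite(res.params["covariate"]) or not np.isfinite(res.bse["covariate"]):
        raise ValueError("fit did not converge to finite estimates (separation?)")

    beta = float(res.params["covariate"])
    se = float(res.bse["covariate"])
    if measure in ("OR", "IRR"):
        est = float(np.exp(beta))
        lo, hi = float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))
    else:
        est = beta
        lo, hi = beta - Z95 * se, beta + Z95 * se
    return EffectEstimate(
        covariate="covariate",
        model=family,
        measure=measure,
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_blockgroups=len(df),
        n_counties=n_counties,
        n_counties_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# concentration curves and index
# ---------------------------------------------------------------------------

def concentration_curve(rank_values, burdens) -> np.ndarray:
    """Piecewise-linear concentration curve from (0,0) to (1,1).

    Block groups are ordered by *descending* ``rank_values`` (most
    marginalized first; ties broken by stable input order); x is the
    cumulative share of block groups, y the cumulative share of total
    burden.
    """
    rank_values = np.asarray(rank_values, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if rank_values.shape != burdens.shape or rank_values.ndim != 1:
        raise ValueError("rank_values and burdens must be equal-length 1-D arrays")
    if np.any(burdens < 0):
        raise ValueError("burdens must be nonnegative")
    total = burdens.sum()
    if total == 0:
        raise ValueError("all burdens are zero: curve undefined")
    order = np.argsort(-rank_values, kind="stable")
    n = len(order)
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(burdens[order]) / total])
    y[-1] = 1.0
    return np.column_stack([x, y])


def concentration_index(curve: np.ndarray) -> float:
    """C = 1 − 2·A where A is the trapezoid area under the curve.

    With descending ordering, a curve above the diagonal (burden
    concentrated among the more marginalized) has A > 1/2 and C < 0.
    """
    curve = np.asarray(curve, dtype=float)
    x, y = curve[:, 0], curve[:, 1]
    area = float(np.trapezoid(y, x))
    return 1.0 - 2.0 * area


def concentration_ci(
    rank_values,
    burdens,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the concentration index.

    Resamples block groups with replacement; deterministic for a fixed
    seed. All-zero resamples (possible with sparse burdens) are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rank_values = np.asarray(rank_values, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    n = len(rank_values)
    if n < 10:
        raise ValueError("bootstrap CI needs at least 10 block groups")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if burdens[idx].sum() > 0:
                break
        out[b] = concentration_index(
            concentration_curve(rank_values[idx], burdens[idx])
        )
    lo, hi = np.percentile(out, [2.5, 97.5])
    return float(lo), float(hi)


def concentration_analysis(
    rank_values,
    burdens,
    covariate: str = "covariate",
    category: str = "all",
    metric: str = "n_sites",
    n_boot: int = 1000,
    seed: int = 0,
) -> ConcentrationResult:
    """Curve, index, and bootstrap CI in one shot."""
    curve = concentration_curve(rank_values, burdens)
    c = concentration_index(curve)
    lo, hi = concentration_ci(rank_values, burdens, n_boot=n_boot, seed=seed)
    return ConcentrationResult(covariate, category, metric, c, lo, hi, curve)
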