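"""Annual flood-exceedance probabilities under probabilistic sea-level rise.

The flood climatology at a tide gauge is a Poisson–generalized-Pareto
(GPD) return curve: flood events whose still-water height exceeds a
gauge-specific threshold ``mu`` (m above mean higher high water, MHHW)
arrive at a mean rate ``lambda`` per year, and exceedance heights above
the threshold follow a GPD with scale ``sigma`` and shape ``xi``.  The
expected number of floods per year exceeding a height ``z`` is

    N0(z) = lambda * [1 + xi * (z - mu) / sigma]^(-1/xi)   for z >= mu,

with the exponential-tail limit ``lambda * exp(-(z - mu)/sigma)`` as
``xi -> 0`` and zero beyond the finite upper endpoint when ``xi < 0``.
Below the threshold the curve is extended log-linearly down to a
capped rate at 0 m MHHW (order daily high tides), constant below 0 m.

Sea-level rise of amount ``s`` shifts the effective freeboard of a site
at elevation ``z`` to ``z - s``.  Integrating over a probabilistic SLR
projection (an array of equally weighted samples) by the law of total
probability gives the amplified expected count

    N_e(z) = E_s[ N0(z - s) ],

and, under Poisson arrivals, the annual probability of at least one
flood ``p = 1 - exp(-N_e)``.  A site is classified *at risk* when this
annual probability reaches the 1-in-100-year criterion (p >= 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: default sub-threshold cap: order of magnitude of daily high tides (events/yr)
DEFAULT_CAP_RATE = 182.6

#: at-risk classification threshold on the annual flood probability
AT_RISK_P = 0.01

_XI_TOL = 1e-8


@dataclass(frozen=True)
class FloodReturnCurve:
    """Poisson–GPD flood return curve for one tide gauge."""

    gauge_id: str
    lambda_rate: float   # mean annual count of threshold exceedances (events/yr)
    threshold_mu: float  # GPD threshold height (m above MHHW)
    scale_sigma: float   # GPD scale (m)
    shape_xi: float      # GPD shape (dimensionless)
    cap_rate: float = DEFAULT_CAP_RATE  # annual flood count at/below 0 m MHHW
    x: float = 0.0       # gauge coordinates (m, planar)
    y: float = 0.0

    def __post_init__(self) -> None:
        if not self.lambda_rate > 0:
            raise ValueError("lambda_rate must be positive")
        if not self.scale_sigma > 0:
            raise ValueError("scale_sigma must be positive")
        if not self.cap_rate >= self.lambda_rate:
            raise ValueError("cap_rate must be >= lambda_rate")
        if not self.threshold_mu >= 0:
            raise ValueError("threshold_mu must be >= 0 (m above MHHW)")

    @property
    def upper_endpoint(self) -> float:
        """Finite upper endpoint of the GPD support (inf when xi >= 0)."""
        if self.shape_xi < -_XI_TOL:
            return self.threshold_mu - self.scale_sigma / self.shape_xi
        return np.inf


def expected_exceedances(z, curve: FloodReturnCurve):
    """Expected annual count of floods exceeding height ``z`` (m MHHW).

    Vectorized over ``z``.  Above the GPD threshold the Poisson–GPD
    form applies; between 0 m and the threshold the curve is a
    log-linear interpolation between ``(0, cap_rate)`` and
    ``(threshold_mu, lambda_rate)``; at or below 0 m it is the constant
    ``cap_rate``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("height z must be finite")
    scalar = z.ndim == 0
    z = np.atleast_1d(z)

    lam, mu, sig, xi = (
        curve.lambda_rate,
        curve.threshold_mu,
        curve.scale_sigma,
        curve.shape_xi,
    )
    out = np.empty_like(z)

    above = z >= mu
    t = (z[above] - mu) / sig
    if abs(xi) < _XI_TOL:
        out[above] = lam * np.exp(-t)
    else:
        base = 1.0 + xi * t
        with np.errstate(invalid="ignore"):
            n = np.where(base > 0.0, lam * np.maximum(base, 0.0) ** (-1.0 / xi), 0.0)
        out[above] = n

    below = ~above
    if mu > 0:
        zb = np.clip(z[below], 0.0, None)
        # log-linear in N between (0, cap) and (mu, lambda)
        log_n = np.log(curve.cap_rate) + (zb / mu) * (np.log(lam) - np.log(curve.cap_rate))
        out[below] = np.exp(log_n)
    else:
        out[below] = curve.cap_rate
    out[z <= 0.0] = curve.cap_rate

    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SLRProjection:
    """Sample-based local sea-level-rise distribution for gauge x scenario x year.

    Samples are in meters relative to current MHHW and include vertical
    land movement.
    """

    gauge_id: str
    scenario: str  # "RCP45" | "RCP85"
    year: int      # 2050 | 2100
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size < 100:
            raise ValueError("SLR projection requires >= 100 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("SLR samples must be finite")


@dataclass(frozen=True)
class SiteRisk:
    site_id: str
    scenario: str
    year: int
    expected_floods: float
    p_annual: float
    at_risk: bool


def annual_flood_probability(
    elevation_q25: float, slr: SLRProjection, curve: FloodReturnCurve
) -> tuple[float, float]:
    """(expected annual flood count, annual probability of >=1 flood).

    The expected count integrates the return curve over the full SLR
    sample array by the sample mean (law of total probability); no
    subsampling is applied.
    """
    if slr.gauge_id != curve.gauge_id:
        raise ValueError(
            f"gauge mismatch: SLR projection for {slr.gauge_id!r}, "
            f"curve for {curve.gauge_id!r}"
        )
    n_e = float(np.mean(expected_exceedances(elevation_q25 - slr.samples, curve)))
    p = -np.expm1(-n_e)
    return n_e, float(p)


def classify_at_risk(p_annual: float, threshold: float = AT_RISK_P) -> bool:
    """True iff the annual flood probability meets the 1-in-100-yr criterion."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError("p_annual must lie in [0, 1]")
    return p_annual >= threshold


def site_risk_table(
    sites,
    slr_set: Iterable[SLRProjection],
    curves: Iterable[FloodReturnCurve],
    scenario: str,
    year: int,
) -> pd.DataFrame:
    """Per-site flood risk for one scenario and year.

    ``sites`` is an iterable of objects (or mapping rows) carrying
    ``site_id``, ``category``, ``gauge_id`` and ``elevation_q25``.
    Returns a DataFrame with one row per site.
    """
    curve_by_gauge = {c.gauge_id: c for c in curves}
    slr_by_gauge = {
        p.gauge_id: p for p in slr_set if p.scenario == scenario and p.year == year
    }
    rows = []
    for site in sites:
        get = site.get if isinstance(site, dict) else lambda k, s=site: getattr(s, k)
        gauge = get("gauge_id")
        if gauge not in curve_by_gauge:
            raise KeyError(f"no return curve for gauge {gauge!r}")
        if gauge not in slr_by_gauge:
            raise KeyError(
                f"no SLR projection for gauge {gauge!r} under {scenario}/{year}"
            )
        n_e, p = annual_flood_probability(
            get("elevation_q25"), slr_by_gauge[gauge], curve_by_gauge[gauge]
        )
        rows.append(
            {
                "site_id": get("site_id"),
                "category": get("category"),
                "scenario": scenario,
                "year": year,
                "expected_floods": n_e,
                "p_annual": p,
                "at_risk": classify_at_risk(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "category",
            "scenario",
            "year",
            "expected_floods",
            "p_annual",
            "at_risk",
        ],
    )
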