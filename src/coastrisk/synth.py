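"""Synthetic coastal study regions with known generative truth.

Real inputs to the hazard-equity analysis (facility registries, tax
parcels, lidar elevation, tide-gauge return curves, localized SLR
projections, census geographies, gridded population) are large and
partly proprietary. This module builds self-contained planar regions
that carry the *statistical structure* the analysis assumes, so every
downstream stage can be exercised and validated against known truth:

* a DEM ramping from 0 m at a wavy coastline to above 18 m inland, with
  spatially correlated noise;
* counties tiled in a coastal and an inland layer (so some counties
  contain low-lying land and some do not) and block groups nested
  exactly one-per-county-strip inside them;
* Poisson–GPD tide gauges along the coast and right-skewed, sample-based
  SLR distributions per gauge × scenario × year whose location grows
  with time and emissions;
* hazardous-site records clustered near the coast, with injected
  near-duplicates, offshore wells, FUDS point/polygon mixtures, and
  messy address strings to exercise fuzzy matching;
* block-group demographics in which one chosen marginalization
  covariate is tied to exposure through a logistic model with county
  intercepts and a *known* standardized log-odds slope.

Everything is a pure function of (config, seed); generative parameters
are recorded in ``SyntheticRegion.truth`` for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize, special
from shapely.geometry import LineString, Point, Polygon, box

from .flood import DEFAULT_CAP_RATE, FloodReturnCurve, SLRProjection
from .grid import Grid
from .ingest import RawSiteRecord

SCENARIOS = ("RCP45", "RCP85")
YEARS = (2050, 2100)

#: median local sea-level rise (m) by scenario and year; right-skewed
#: spread is added around these central values per gauge.
SLR_MEDIANS_M = {
    ("RCP45", 2050): 0.24,
    ("RCP45", 2100): 0.55,
    ("RCP85", 2050): 0.29,
    ("RCP85", 2100): 0.90,
}

_STREETS = (
    "MAIN", "OCEAN", "HARBOR", "BAY", "SHORE", "MARSH", "DELTA", "CANAL",
    "LEVEE", "PORT", "INDUSTRIAL", "REFINERY", "DOCK", "TIDE", "GULF",
)
_SUFFIXES = ("ST", "AVE", "RD", "BLVD", "LN", "WAY")

#: representative rulebook hint per category (see ingest.DEFAULT_RULEBOOK)
CATEGORY_HINTS = {
    "power_plant": "NAICS:2211",
    "animal_operation": "CAFO",
    "sewage_treatment": "NPDES-POTW",
    "hazardous_waste_tsd": "RCRA-TSD",
    "tri_industrial": "TRI",
    "solid_waste": "LANDFILL",
    "cleanup_radioactive": "NPL",
    "refinery": "NAICS:32411",
    "fossil_port_terminal": "PORT",
    "oil_gas_well": "WELL",
    "fuds": "FUDS",
}

DEFAULT_SITES_PER_CATEGORY = {
    "power_plant": 6,
    "animal_operation": 8,
    "sewage_treatment": 10,
    "hazardous_waste_tsd": 6,
    "tri_industrial": 30,
    "solid_waste": 8,
    "cleanup_radioactive": 6,
    "refinery": 4,
    "fossil_port_terminal": 8,
    "oil_gas_well": 40,
    "fuds": 8,
}


@dataclass(frozen=True)
class RegionConfig:
    """Knobs of the synthetic region generator."""

    seed: int = 0
    extent_m: tuple[float, float] = (30000.0, 20000.0)  # width (inland) x height
    cell_m: float = 30.0
    n_counties: int = 6
    n_blockgroups: int = 120
    n_sites_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_CATEGORY)
    )
    duplicate_rate: float = 0.08
    n_gauges: int = 3
    slr_samples: int = 1000
    slr_spread: float = 0.15   # scale of right-skewed spread; 0 → degenerate
    assoc_log_odds: float = math.log(1.4)
    assoc_covariate: str = "pct_poverty"
    with_popgrid: bool = True  # False exercises the block-group-only fallback

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")
        if w / self.cell_m < 2 or h / self.cell_m < 2:
            raise ValueError("degenerate extent: fewer than 4 DEM cells")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.slr_samples < 100:
            raise ValueError("slr_samples must be at least 100")
        if self.n_blockgroups < self.n_counties:
            raise ValueError("need at least one block group per county")
        if self.n_counties < 1:
            raise ValueError("need at least one county")


@dataclass
class SyntheticRegion:
    config: RegionConfig
    dem: Grid
    coastline: LineString
    land: Polygon
    counties: dict[str, Polygon]
    blockgroups: list  # exposure.BlockGroup once demographics exist
    popgrid: Grid | None
    gauges: list[FloodReturnCurve]
    slr: list[SLRProjection]
    raw_sites: list[RawSiteRecord]
    parcels: list[Polygon]
    fuds_polygons: list[tuple[str, Polygon]]
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# terrain, counties, block groups
# ---------------------------------------------------------------------------

def _coast_x(y: np.ndarray, width: float, height: float, rng: np.random.Generator):
    """Wavy coastline x-position as a function of y."""
    base = 0.12 * width
    amp = 0.03 * width
    phase = rng.uniform(0, 2 * math.pi)
    return base + amp * np.sin(2 * math.pi * y / (0.8 * height) + phase)


def make_region(config: RegionConfig) -> SyntheticRegion:
    """Terrain, administrative geography, gauges and SLR (no sites yet).

    The DEM ramps linearly from 0 m at the coastline to above 18 m
    inland with spatially correlated Gaussian noise; cells seaward of
    the coastline are below 0 m (water).
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.extent_m
    cell = config.cell_m
    ncols = int(round(width / cell))
    nrows = int(round(height / cell))

    xs = (np.arange(ncols) + 0.5) * cell
    ys = height - (np.arange(nrows) + 0.5) * cell
    X, Y = np.meshgrid(xs, ys)

    coast = _coast_x(Y, width, height, rng)
    # slope: reach ~28 m at the far edge so the inland county tier (east of
    # 0.75*width) sits entirely above the 18-m study threshold
    slope = 28.0 / (width - float(coast.max()))
    noise = rng.normal(0.0, 1.0, size=(nrows, ncols))
    noise = ndimage.gaussian_filter(noise, sigma=6.0, mode="reflect")
    noise *= 0.6 / max(noise.std(), 1e-12)
    elev = slope * (X - coast) + noise
    # keep the noise from flipping the land/water sign right at the coast
    elev = np.where(X >= coast, np.maximum(elev, 0.01), np.minimum(elev, -0.01))
    dem = Grid(values=elev, xmin=0.0, ymin=0.0, cell=cell)

    # coastline polyline and land polygon (east of the line); the fresh rng
    # replays the same phase draw the DEM's coastline used above
    y_line = np.linspace(0.0, height, max(nrows, 2))
    x_line = _coast_x(y_line, width, height, np.random.default_rng(config.seed))
    coastline = LineString(np.column_stack([x_line, y_line]))
    land = Polygon(
        [(width, 0.0), (width, height)]
        + list(zip(x_line[::-1], y_line[::-1]))
    ).buffer(0)

    counties = _tile_counties(config, width, height)
    bg_polys = _tile_blockgroups(config, counties)

    gauges = _make_gauges(config, x_line, y_line, rng)
    slr = make_slr_projections(
        gauges,
        SCENARIOS,
        YEARS,
        seed=int(rng.integers(2**31)),
        n_samples=config.slr_samples,
        spread=config.slr_spread,
    )

    region = SyntheticRegion(
        config=config,
        dem=dem,
        coastline=coastline,
        land=land,
        counties=counties,
        blockgroups=[],
        popgrid=None,
        gauges=gauges,
        slr=slr,
        raw_sites=[],
        parcels=[],
        fuds_polygons=[],
        truth={
            "slr_medians": {
                (p.gauge_id, p.scenario, p.year): float(np.median(p.samples))
                for p in slr
            },
            "bg_polys": bg_polys,
        },
    )
    return region


def _tile_counties(config: RegionConfig, width: float, height: float):
    """Two-layer tiling: a coastal column and an inland column of strips.

    The inland column starts far enough east that its land sits above
    the 18-m line, so the study-county restriction has something to
    exclude.
    """
    n = config.n_counties
    counties: dict[str, Polygon] = {}
    if n == 1:
        counties["C00"] = box(0, 0, width, height)
        return counties
    n_coastal = (n + 1) // 2
    n_inland = n - n_coastal
    x_split = 0.75 * width
    for i in range(n_coastal):
        y0 = height * i / n_coastal
        y1 = height * (i + 1) / n_coastal
        counties[f"C{i:02d}"] = box(0, y0, x_split, y1)
    for i in range(n_inland):
        y0 = height * i / n_inland
        y1 = height * (i + 1) / n_inland
        counties[f"C{n_coastal + i:02d}"] = box(x_split, y0, width, y1)
    return counties


def _tile_blockgroups(config: RegionConfig, counties: Mapping[str, Polygon]):
    """Partition each county into vertical strips: exact total count."""
    ids = list(counties)
    areas = np.array([counties[c].area for c in ids])
    n = config.n_blockgroups
    alloc = np.maximum(1, np.floor(n * areas / areas.sum()).astype(int))
    while alloc.sum() > n:
        alloc[int(np.argmax(alloc))] -= 1
    while alloc.sum() < n:
        alloc[int(np.argmin(alloc))] += 1
    out: list[tuple[str, str, Polygon]] = []
    k = 0
    for cid, n_bg in zip(ids, alloc):
        minx, miny, maxx, maxy = counties[cid].bounds
        edges = np.linspace(minx, maxx, n_bg + 1)
        for j in range(n_bg):
            out.append((f"BG{k:04d}", cid, box(edges[j], miny, edges[j + 1], maxy)))
            k += 1
    return out


def _make_gauges(config, x_line, y_line, rng) -> list[FloodReturnCurve]:
    gauges = []
    n = config.n_gauges
    for i in range(n):
        frac = (i + 0.5) / n
        idx = int(frac * (len(y_line) - 1))
        gauges.append(
            FloodReturnCurve(
                gauge_id=f"G{i:02d}",
                lambda_rate=float(rng.uniform(2.0, 5.0)),
                threshold_mu=float(rng.uniform(0.5, 1.0)),
                scale_sigma=float(rng.uniform(0.10, 0.25)),
                shape_xi=float(rng.uniform(-0.10, 0.15)),
                cap_rate=DEFAULT_CAP_RATE,
                x=float(x_line[idx]),
                y=float(y_line[idx]),
            )
        )
    return gauges


# ---------------------------------------------------------------------------
# SLR projections
# ---------------------------------------------------------------------------

def make_slr_projections(
    gauges: Sequence[FloodReturnCurve],
    scenarios: Sequence[str] = SCENARIOS,
    years: Sequence[int] = YEARS,
    seed: int = 0,
    n_samples: int = 1000,
    spread: float = 0.15,
) -> list[SLRProjection]:
    """Right-skewed SLR sample distributions per gauge × scenario × year.

    Samples are a central value (scenario/year median plus a small
    per-gauge vertical-land-movement offset) plus a median-centered
    lognormal deviation scaled by ``spread``; ``spread=0`` gives
    degenerate (all-equal) distributions for exact-truth tests.
    """
    if not gauges:
        raise ValueError("gauge list must be nonempty")
    bad = set(scenarios) - set(SCENARIOS)
    if bad:
        raise ValueError(f"unknown scenarios {sorted(bad)}")
    bad_years = set(years) - set(YEARS)
    if bad_years:
        raise ValueError(f"unsupported years {sorted(bad_years)}")
    rng = np.random.default_rng(seed)
    out = []
    for g in gauges:
        vlm = float(rng.normal(0.0, 0.03))
        for scen in scenarios:
            for yr in years:
                med = SLR_MEDIANS_M[(scen, yr)] + vlm
                if spread > 0:
                    raw = rng.lognormal(mean=0.0, sigma=0.6, size=n_samples)
                    dev = spread * (raw - 1.0)  # median-centered, right-skewed
                else:
                    dev = np.zeros(n_samples)
                out.append(
                    SLRProjection(
                        gauge_id=g.gauge_id,
                        scenario=scen,
                        year=yr,
                        samples=med + dev,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# sites, parcels, population, demographics
# ---------------------------------------------------------------------------

def _perturb_address(addr: str, rng) -> str:
    """Abbreviation / casing / typo operators for near-duplicate records."""
    ops = []
    if " STREET" in addr or " ST" in addr:
        ops.append(lambda a: a.replace(" ST", " STREET") if a.endswith("ST") else a.replace(" STREET", " ST"))
    ops.append(lambda a: a.title())
    ops.append(lambda a: a.lower())

    def typo(a: str) -> str:
        if len(a) < 5:
            return a
        i = int(rng.integers(1, len(a) - 1))
        return a[:i] + a[i + 1 :]

    ops.append(typo)
    op = ops[int(rng.integers(len(ops)))]
    return op(addr)


def _random_address(rng) -> str:
    return (
        f"{int(rng.integers(1, 9999))} "
        f"{_STREETS[int(rng.integers(len(_STREETS)))]} "
        f"{_SUFFIXES[int(rng.integers(len(_SUFFIXES)))]}"
    )


def _gpd_expected_count(z: float, g: FloodReturnCurve) -> float:
    """Generator-side closed-form annual exceedance count (independent of
    the flood module: used only to record generative truth)."""
    lam, mu, sig, xi = g.lambda_rate, g.threshold_mu, g.scale_sigma, g.shape_xi
    if z <= 0:
        return g.cap_rate
    if z < mu:
        return math.exp(
            math.log(g.cap_rate) + (z / mu) * (math.log(lam) - math.log(g.cap_rate))
        )
    t = (z - mu) / sig
    if abs(xi) < 1e-8:
        return lam * math.exp(-t)
    base = 1.0 + xi * t
    if base <= 0:
        return 0.0
    return lam * base ** (-1.0 / xi)


def make_sites_and_demographics(
    region: SyntheticRegion, config: RegionConfig | None = None
) -> SyntheticRegion:
    """Populate the region with raw site records, parcels, population and
    demographics; records generative truth.

    Site density decays inland (industrial land use hugs the coast).
    Near-duplicates, offshore wells, messy addresses and FUDS
    point/polygon mixtures are injected per config. The chosen
    marginalization covariate is drawn *conditional on* each block
    group's true exposure status so that exposure follows a logistic
    model with county intercepts and standardized slope equal to
    ``config.assoc_log_odds`` exactly.
    """
    from .exposure import BlockGroup, blockgroup_exposure  # local: avoid cycle

    config = config or region.config
    rng = np.random.default_rng(config.seed + 1)
    width, height = config.extent_m

    y_line = np.linspace(0.0, height, 256)
    coast_interp = lambda y: float(  # noqa: E731
        np.interp(y, [p[1] for p in region.coastline.coords], [p[0] for p in region.coastline.coords])
    )

    records: list[RawSiteRecord] = []
    fuds_polygons: list[tuple[str, Polygon]] = []
    rid = 0

    def new_id() -> str:
        nonlocal rid
        rid += 1
        return f"R{rid:05d}"

    for category, n in config.n_sites_per_category.items():
        hint = CATEGORY_HINTS[category]
        for _ in range(n):
            y = float(rng.uniform(0, height))
            xc = coast_interp(y)
            x = min(xc + float(rng.exponential(0.22 * width)) + 50.0, width - 50.0)
            addr = _random_address(rng)
            extra_hint = ("TRI",) if category != "tri_industrial" and rng.random() < 0.1 else ()
            records.append(
                RawSiteRecord(
                    record_id=new_id(),
                    source="SYNTH",
                    address=addr,
                    x=x,
                    y=y,
                    hints=(hint,) + extra_hint,
                    active=bool(rng.random() < 0.8),
                    end_year=None if rng.random() < 0.9 else int(rng.integers(2000, 2040)),
                    accuracy_m=float(rng.uniform(1, 120)) if rng.random() < 0.3 else None,
                    zip_level=bool(rng.random() < 0.03),
                    remediated=bool(rng.random() < 0.05),
                )
            )
            if category == "fuds":
                # half the FUDS also carry a polygon footprint
                if rng.random() < 0.5:
                    side = float(rng.uniform(300, 900))
                    fuds_polygons.append(
                        (records[-1].record_id, box(x - side / 2, y - side / 2, x + side / 2, y + side / 2))
                    )

    # near-duplicates: same coordinates + category, perturbed address
    n_dup = int(round(config.duplicate_rate * len(records)))
    if n_dup:
        for src in rng.choice(len(records), size=n_dup, replace=False):
            r = records[int(src)]
            records.append(
                RawSiteRecord(
                    record_id=new_id(),
                    source="SYNTH-DUP",
                    address=_perturb_address(r.address, rng),
                    x=r.x,
                    y=r.y,
                    hints=r.hints,
                    active=r.active,
                )
            )

    # offshore wells, seaward of the coastline (and of all block groups)
    n_off = max(2, config.n_sites_per_category.get("oil_gas_well", 0) // 10)
    for _ in range(n_off):
        y = float(rng.uniform(0, height))
        xc = coast_interp(y)
        records.append(
            RawSiteRecord(
                record_id=new_id(),
                source="SYNTH-OFFSHORE",
                address=_random_address(rng),
                x=max(xc - float(rng.uniform(200, 0.5 * xc)), 10.0),
                y=y,
                hints=("WELL",),
            )
        )

    # tax parcels: blocks tiling the coastal strip (most sites fall inside)
    parcels: list[Polygon] = []
    strip_x1 = 0.55 * width
    psize = 600.0
    for x0 in np.arange(0.0, strip_x1, psize):
        for y0 in np.arange(0.0, height, psize):
            if rng.random() < 0.75:
                parcels.append(
                    box(
                        x0 + rng.uniform(0, 60),
                        y0 + rng.uniform(0, 60),
                        x0 + psize - rng.uniform(0, 60),
                        y0 + psize - rng.uniform(0, 60),
                    )
                )

    # --- truth: at-risk status per record, by nearest gauge, degenerate-at-
    # --- median SLR, computed with generator-side closed forms
    gx = np.array([g.x for g in region.gauges])
    gy = np.array([g.y for g in region.gauges])
    truth_at_risk: dict[tuple[str, int], set[str]] = {}
    site_points: dict[str, tuple[float, float]] = {}
    for scen in SCENARIOS:
        for yr in YEARS:
            truth_at_risk[(scen, yr)] = set()
    p_true_85_2100: dict[str, float] = {}
    for r in records:
        try:
            z = region.dem.value_at(r.x, r.y)
        except IndexError:
            continue
        site_points[r.record_id] = (r.x, r.y)
        k = int(np.argmin((gx - r.x) ** 2 + (gy - r.y) ** 2))
        g = region.gauges[k]
        for scen in SCENARIOS:
            for yr in YEARS:
                med = region.truth["slr_medians"][(g.gauge_id, scen, yr)]
                n_e = _gpd_expected_count(z - med, g)
                p = 1.0 - math.exp(-n_e)
                if p >= 0.01:
                    truth_at_risk[(scen, yr)].add(r.record_id)
                if scen == "RCP85" and yr == 2100:
                    p_true_85_2100[r.record_id] = p

    # --- block groups: population, popgrid, demographics ------------------
    bg_polys = region.truth["bg_polys"]
    blockgroups: list[BlockGroup] = []
    land = region.land
    populations = rng.lognormal(mean=7.0, sigma=0.5, size=len(bg_polys))
    for (bg_id, cid, poly), pop in zip(bg_polys, populations):
        # census geographies terminate at the coastline: clip to land and
        # drop fully offshore strips
        land_part = poly.intersection(land)
        if land_part.is_empty or land_part.area == 0:
            continue
        blockgroups.append(
            BlockGroup(
                bg_id=bg_id,
                county_id=cid,
                geometry=land_part,
                population=float(pop),
            )
        )

    popgrid = _scatter_population(region, blockgroups, rng) if config.with_popgrid else None

    # --- true exposure (1 km, RCP85/2100, truth at-risk set) --------------
    at_risk_pts = [
        (sid, Point(*site_points[sid]), p_true_85_2100[sid])
        for sid in sorted(truth_at_risk[("RCP85", 2100)])
        if sid in site_points
    ]
    exposed = np.array(
        [
            blockgroup_exposure(bg, at_risk_pts, 1000.0, popgrid)["exposed"]
            for bg in blockgroups
        ]
    )
    county_idx = np.array([list(region.counties).index(bg.county_id) for bg in blockgroups])

    # --- marginalization covariate conditional on exposure ----------------
    x_std, intercepts = _covariate_given_exposure(
        exposed, county_idx, config.assoc_log_odds, rng
    )
    assoc_prop = np.clip(0.3 + 0.1 * x_std, 0.0, 1.0)

    for i, bg in enumerate(blockgroups):
        cov = _draw_background_covariates(rng)
        cov[config.assoc_covariate] = float(assoc_prop[i])
        cov["cejst_disadvantaged"] = float(
            rng.random() < special.expit(2.0 * (cov["pct_poverty"] - 0.3) / 0.1 - 1.0)
        )
        bg.covariates = cov

    region.raw_sites = records
    region.parcels = parcels
    region.fuds_polygons = fuds_polygons
    region.blockgroups = blockgroups
    region.popgrid = popgrid
    region.truth.update(
        {
            "at_risk_sites": truth_at_risk,
            "p_annual_rcp85_2100": p_true_85_2100,
            "assoc_log_odds": config.assoc_log_odds,
            "assoc_covariate": config.assoc_covariate,
            "county_intercepts": intercepts,
            "true_exposed_bg": {
                bg.bg_id for bg, e in zip(blockgroups, exposed) if e
            },
        }
    )
    return region


def _draw_background_covariates(rng) -> dict[str, float]:
    race = rng.dirichlet([2.0, 1.2, 0.8, 0.3, 0.2, 4.0])  # last = white, dropped
    cov = {
        "pct_renters": float(rng.beta(2.0, 3.0)),
        "pct_hispanic": float(race[0]),
        "pct_black": float(race[1]),
        "pct_asian_pi": float(race[2]),
        "pct_native": float(race[3]),
        "pct_other_poc": float(race[4]),
        "pct_linguistic_isolation": float(rng.beta(1.2, 8.0)),
        "pct_no_vehicle": float(rng.beta(1.5, 6.0)),
        "pct_single_parent": float(rng.beta(2.0, 8.0)),
        "pct_under_18": float(rng.beta(4.0, 14.0)),
        "pct_over_65": float(rng.beta(3.0, 9.0)),
        "pct_nonvoter": float(rng.beta(3.0, 7.0)),
    }
    return cov


def _scatter_population(region: SyntheticRegion, blockgroups, rng) -> Grid:
    """30-m population raster: block-group totals spread over land cells
    with density decaying from the block-group centroid; zero over water."""
    dem = region.dem
    pop = np.zeros_like(dem.values)
    xs, ys = dem.cell_centers()
    land_mask = dem.values > 0.0
    for bg in blockgroups:
        if bg.population <= 0:
            continue
        minx, miny, maxx, maxy = bg.geometry.bounds
        sel = (
            land_mask
            & (xs >= minx)
            & (xs < maxx)
            & (ys >= miny)
            & (ys < maxy)
        )
        if not sel.any():
            continue
        cx, cy = bg.geometry.centroid.x, bg.geometry.centroid.y
        d = np.hypot(xs[sel] - cx, ys[sel] - cy)
        w = np.exp(-d / 1500.0)
        # thin to a subset of populated cells so empty land exists
        keep = rng.random(w.size) < 0.35
        if not keep.any():
            keep[int(np.argmax(w))] = True
        w = np.where(keep, w, 0.0)
        pop_cells = bg.population * w / w.sum()
        flat = pop.copy()
        flat[sel] += pop_cells
        pop = flat
    return Grid(values=pop, xmin=dem.xmin, ymin=dem.ymin, cell=dem.cell)


def _covariate_given_exposure(exposed, county_idx, b, rng):
    """Draw a standardized covariate so exposure follows a county-intercept
    logistic model with slope ``b`` exactly.

    For each county the intercept ``a_c`` solves
    ``E_{x~N(0,1)}[expit(a_c + b x)] = empirical exposure rate``; given
    the realized exposure labels, ``x`` is drawn from the Bayes
    conditional ``f(x | E)`` by rejection against the N(0,1) envelope.
    """
    exposed = np.asarray(exposed, dtype=bool)
    county_idx = np.asarray(county_idx)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal_rate(a: float) -> float:
        return float(np.sum(weights * special.expit(a + b * nodes)))

    intercepts: dict[int, float] = {}
    for c in np.unique(county_idx):
        rate = float(np.clip(exposed[county_idx == c].mean(), 0.02, 0.98))
        if abs(b) < 1e-12:
            intercepts[int(c)] = float(special.logit(rate))
            continue
        intercepts[int(c)] = float(
            optimize.brentq(lambda a: marginal_rate(a) - rate, -20.0, 20.0)
        )

    x = np.empty(len(exposed))
    for i, (e, c) in enumerate(zip(exposed, county_idx)):
        a = intercepts[int(c)]
        while True:
            cand = rng.normal()
            accept_p = special.expit(a + b * cand)
            if not e:
                accept_p = 1.0 - accept_p
            if rng.random() < accept_p:
                x[i] = cand
                break
    return x, intercepts


# ---------------------------------------------------------------------------
# lightweight tabular generator (no geometry): parameter-recovery studies
# ---------------------------------------------------------------------------

def simulate_exposure_covariates(
    n_blockgroups: int,
    n_counties: int,
    assoc_log_odds: float,
    seed: int,
    base_rate: float = 0.22,
    county_sd: float = 0.5,
    density_log_odds: float = 0.2,
    nb_alpha: float = 0.4,
):
    """Forward-simulate the exposure/covariate table the regressions see.

    Block groups get a standard-normal marginalization covariate and a
    lognormal density; exposure is Bernoulli under a logistic model with
    county intercepts (drawn around ``logit(base_rate)``), the covariate
    slope, and a density slope. Among exposed block groups the at-risk
    site count is 1 + NB2 and EAE sums per-site probabilities.

    Returns a DataFrame with columns ``county, x, density_z, exposed,
    n_sites, eae``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    county = rng.integers(0, n_counties, size=n_blockgroups)
    a_c = special.logit(base_rate) + rng.normal(0.0, county_sd, size=n_counties)
    x = rng.normal(size=n_blockgroups)
    density_z = rng.normal(size=n_blockgroups)
    eta = a_c[county] + assoc_log_odds * x + density_log_odds * density_z
    exposed = rng.random(n_blockgroups) < special.expit(eta)

    mu_count = np.exp(0.3 + 0.5 * assoc_log_odds * x)
    extra = rng.negative_binomial(
        n=1.0 / nb_alpha, p=1.0 / (1.0 + nb_alpha * mu_count)
    )
    n_sites = np.where(exposed, 1 + extra, 0)
    p_bar = rng.uniform(0.01, 0.6, size=n_blockgroups)
    eae = n_sites * p_bar

    return pd.DataFrame(
        {
            "county": county,
            "x": x,
            "density_z": density_z,
            "exposed": exposed.astype(int),
            "n_sites": n_sites,
            "eae": eae,
        }
    )
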