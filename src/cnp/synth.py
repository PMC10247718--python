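"""Synthetic world generator.

Builds a complete, internally consistent miniature "country" —
provinces, counties on a raster grid, crop sown areas, fertilizer rates
with known ground truth — so that every pipeline stage can be tested
end to end without the (non-redistributable) statistical yearbooks.

The defaults emulate the real study conditions: 31 provinces, roughly
2200 counties, years 2004-2016, four crop categories, sporadic missing
county-years in runs of at most two, and base rates/growth chosen so
national P2O5 means and trends land in the magnitude range of the
published dataset (wheat highest at ~8-9 g/m2, maize the fastest-rising
trend).  Counties are rectangular tiles on the grid; the county-ID
raster assigns each pixel to the tile containing its center, with no
dependence on real administrative boundaries.

Two world flavors matter for testing.  In the *provincial-uniform*
flavor every county shares its province's rates, and the ratio
allocation recovers county rates exactly — the regime where the method
is provably exact.  In the *heterogeneous* flavor county truth varies
within a province; allocation then conserves county totals but cannot
recover per-crop county truth, so tests must only assert aggregate
consistency.  Underlying time series are low-order polynomials plus
small seeded noise, so spline gap-filling has a quantifiable truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .convert import CompositionWeights
from .errors import CnpError
from .grid import GridGeometry
from .tables import (
    ALL_CROPS,
    CROPLAND_AREA,
    CountyStats,
    KINDS,
    NAMED_CROPS,
    ProvincialRates,
    ProvincialTotals,
    Status,
    TOTAL_AREA,
)

#: nominal area of one grid pixel (m2); the synthetic grid is an
#: abstraction, not a geodesic model
PIXEL_AREA_M2 = 1.0e6

#: base 2004 rates (g/m2 of each kind's own reporting basis) per crop,
#: and relative annual growth per crop, applied to both kinds
BASE_RATE = {
    "phosphorus": {"rice": 3.6, "wheat": 5.0, "maize": 3.3, "other": 2.8},
    "component": {"rice": 5.3, "wheat": 7.3, "maize": 5.1, "other": 4.5},
}
GROWTH = {"rice": 0.020, "wheat": 0.014, "maize": 0.032, "other": 0.022}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; identical seed+config gives a
    bit-identical world."""

    n_provinces: int = 31
    counties_per_province: tuple[int, int] = (60, 80)
    years: tuple[int, int] = (2004, 2016)
    grid_rows: int = 200
    grid_cols: int = 240
    pixel_size: float = 0.25
    west: float = 73.0
    north: float = 54.0
    missing_rate: float = 0.05
    max_gap_run: int = 2
    heterogeneous: bool = False
    county_cv: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_provinces < 1 or self.counties_per_province[0] < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is inverted")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass
class GroundTruth:
    """The generator's own record of what is true, per county-year.

    ``rates``/``p2o5`` include only crop-years the county actually
    grows (area > 0).  ``areas`` and ``consumption`` are gap-free.
    """

    rates: pd.DataFrame
    p2o5: pd.DataFrame
    areas: pd.DataFrame
    consumption: pd.DataFrame


@dataclass
class World:
    config: WorldConfig
    truth: GroundTruth
    prov_rates: ProvincialRates
    prov_totals: ProvincialTotals
    county: CountyStats
    county_raster: np.ndarray
    crop_masks: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    geom: GridGeometry | None = None


def _tile_layout(n: int, rows: int, cols: int) -> tuple[int, int, int, int]:
    tiles_x = int(np.ceil(np.sqrt(n * cols / rows))) or 1
    tiles_y = int(np.ceil(n / tiles_x))
    if tiles_y > rows or tiles_x > cols:
        raise CnpError(
            f"grid {rows}x{cols} too small to host {n} counties")
    return tiles_y, tiles_x, rows // tiles_y, cols // tiles_x


def _county_raster(n: int, rows: int, cols: int) -> np.ndarray:
    tiles_y, tiles_x, h, w = _tile_layout(n, rows, cols)
    raster = np.zeros((rows, cols), dtype=np.int32)
    for k in range(n):
        ty, tx = divmod(k, tiles_x)
        raster[ty * h:(ty + 1) * h, tx * w:(tx + 1) * w] = k + 1
    return raster


def _missing_pattern(rng, n_counties: int, n_years: int,
                     rate: float, max_run: int) -> np.ndarray:
    """Boolean (county, year) missingness; interior years only, runs
    capped at max_run."""
    miss = np.zeros((n_counties, n_years), dtype=bool)
    if rate <= 0 or n_years < 3:
        return miss
    for j in range(n_counties):
        run = 0
        for t in range(1, n_years - 1):
            if run >= max_run:
                run = 0
                continue
            if rng.random() < rate:
                miss[j, t] = True
                run += 1
            else:
                run = 0
    return miss


def generate_world(config: WorldConfig | None = None,
                   weights: CompositionWeights | None = None) -> World:
    """Build a world: ground truth, statistics tables, and rasters."""
    config = config or WorldConfig()
    weights = weights or CompositionWeights.default()
    rng = np.random.default_rng(config.seed)
    years = config.year_list
    ny = len(years)
    t = np.arange(ny, dtype=float)
    tn = t / max(ny - 1, 1)

    lo, hi = config.counties_per_province
    per_prov = rng.integers(lo, hi + 1, size=config.n_provinces)
    n = int(per_prov.sum())
    prov_of = np.repeat(np.arange(config.n_provinces), per_prov)  # 0-based
    county_ids = np.arange(1, n + 1)
    prov_ids = np.arange(1, config.n_provinces + 1)

    raster = _county_raster(n, config.grid_rows, config.grid_cols)
    geom = GridGeometry(west=config.west, north=config.north,
                        pixel_size=config.pixel_size,
                        rows=config.grid_rows, cols=config.grid_cols)
    n_pix = np.bincount(raster.ravel(), minlength=n + 1)[1:]
    if (n_pix == 0).any():
        raise CnpError("grid too small to host requested counties")

    nc, nk = len(ALL_CROPS), len(KINDS)
    # provincial rate curves: base * province multiplier * smooth trend * noise
    base = np.array([[BASE_RATE[k][c] for k in KINDS] for c in ALL_CROPS])  # (c,k)
    growth = np.array([GROWTH[c] for c in ALL_CROPS])  # (c,)
    pmult = rng.lognormal(0.0, 0.20, size=(config.n_provinces, nc, nk))
    gjit = growth[None, :] * (1 + 0.15 * rng.standard_normal(
        (config.n_provinces, nc)))
    quad = 0.0008 * rng.standard_normal((config.n_provinces, nc))
    trend = 1 + gjit[..., None] * t + quad[..., None] * t**2  # (p,c,y)
    noise = 1 + config.noise_sd * rng.standard_normal(
        (config.n_provinces, nc, nk, ny))
    prov_curve = (base[None, :, :, None] * pmult[..., None]
                  * trend[:, :, None, :] * noise)
    prov_curve = np.clip(prov_curve, 0.05 * base[None, :, :, None], None)

    # county truth rates (j,c,k,y)
    if config.heterogeneous:
        cmult = np.clip(1 + config.county_cv * rng.standard_normal((n, nc, nk)),
                        0.2, None)
    else:
        cmult = np.ones((n, nc, nk))
    rate_true = prov_curve[prov_of] * cmult[..., None]

    # county areas (j,c,y): share of sown area per category, smooth in time
    sown_frac = rng.uniform(0.3, 0.7, size=n)
    multi = rng.uniform(1.1, 1.5, size=n)
    base_total = n_pix * PIXEL_AREA_M2 * sown_frac * multi
    grows = rng.random((n, len(NAMED_CROPS))) < 0.85
    w_named = rng.uniform(0.5, 1.5, size=(n, len(NAMED_CROPS))) * grows
    w_other = rng.uniform(0.8, 1.6, size=(n, 1))
    w = np.concatenate([w_named, w_other], axis=1)
    shares = w / w.sum(axis=1, keepdims=True)
    a1 = 0.05 * rng.standard_normal((n, nc))
    a2 = 0.03 * rng.standard_normal((n, nc))
    yfac = np.clip(1 + a1[..., None] * tn + a2[..., None] * tn**2, 0.05, None)
    area = (base_total[:, None] * shares)[..., None] * yfac  # (j,c,y)
    total_area = area.sum(axis=1)                            # (j,y)
    cropland = np.repeat((n_pix * PIXEL_AREA_M2 * sown_frac)[:, None], ny, axis=1)

    # consumption: FC_{j,k,y} = sum_c rate * area, fixed crop order
    cons = np.einsum("jcky,jcy->jky", rate_true, area)

    # ---- assemble long tables -------------------------------------------
    jj, cc, yy = np.meshgrid(np.arange(n), np.arange(nc), np.arange(ny),
                             indexing="ij")
    area_long = pd.DataFrame({
        "county": county_ids[jj.ravel()],
        "year": years[yy.ravel()],
        "crop": np.array(ALL_CROPS)[cc.ravel()],
        "area": area.ravel(),
    })
    truth_rates = []
    for ki, kind in enumerate(KINDS):
        d = area_long[["county", "year", "crop"]].copy()
        d["kind"] = kind
        d["rate"] = rate_true[:, :, ki, :].ravel()
        d["area"] = area.ravel()
        truth_rates.append(d)
    truth_rates = pd.concat(truth_rates, ignore_index=True)
    truth_rates = truth_rates[truth_rates["area"] > 0].drop(columns="area")

    content = weights.content_series(years)
    wide = truth_rates.pivot_table(index=["county", "year", "crop"],
                                   columns="kind", values="rate",
                                   aggfunc="first").reset_index()
    truth_p2o5 = pd.DataFrame({
        "county": wide["county"], "year": wide["year"], "crop": wide["crop"],
        "p2o5_rate": wide["phosphorus"]
        + wide["component"] * wide["year"].map(content),
    })

    jj2, yy2 = np.meshgrid(np.arange(n), np.arange(ny), indexing="ij")
    cons_long = []
    for ki, kind in enumerate(KINDS):
        cons_long.append(pd.DataFrame({
            "county": county_ids[jj2.ravel()], "year": years[yy2.ravel()],
            "kind": kind, "consumption": cons[:, ki, :].ravel(),
        }))
    cons_long = pd.concat(cons_long, ignore_index=True)

    truth_areas = pd.concat([
        area_long,
        pd.DataFrame({"county": county_ids[jj2.ravel()],
                      "year": years[yy2.ravel()], "crop": TOTAL_AREA,
                      "area": total_area.ravel()}),
        pd.DataFrame({"county": county_ids[jj2.ravel()],
                      "year": years[yy2.ravel()], "crop": CROPLAND_AREA,
                      "area": cropland.ravel()}),
    ], ignore_index=True)

    truth = GroundTruth(rates=truth_rates, p2o5=truth_p2o5,
                        areas=truth_areas, consumption=cons_long)

    # ---- provincial tables ----------------------------------------------
    prov_area = np.zeros((config.n_provinces, nc, ny))
    prov_wx = np.zeros((config.n_provinces, nc, nk, ny))
    np.add.at(prov_area, prov_of, area)
    np.add.at(prov_wx, prov_of, rate_true * area[:, :, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        prov_rate = prov_wx / prov_area[:, :, None, :]
    prov_total_area = np.zeros((config.n_provinces, ny))
    np.add.at(prov_total_area, prov_of, total_area)
    prov_cons = np.zeros((config.n_provinces, nk, ny))
    np.add.at(prov_cons, prov_of, cons)

    pp, cc2, yy3 = np.meshgrid(np.arange(config.n_provinces),
                               np.arange(len(NAMED_CROPS)), np.arange(ny),
                               indexing="ij")
    prov_rates_rows = []
    for ki, kind in enumerate(KINDS):
        prov_rates_rows.append(pd.DataFrame({
            "province": prov_ids[pp.ravel()], "year": years[yy3.ravel()],
            "crop": np.array(NAMED_CROPS)[cc2.ravel()], "kind": kind,
            "rate": prov_rate[:, :len(NAMED_CROPS), ki, :].ravel(),
        }))
    prov_rates_df = pd.concat(prov_rates_rows, ignore_index=True).dropna(
        subset=["rate"])

    pp2, yy4 = np.meshgrid(np.arange(config.n_provinces), np.arange(ny),
                           indexing="ij")
    prov_cons_rows = []
    for ki, kind in enumerate(KINDS):
        prov_cons_rows.append(pd.DataFrame({
            "province": prov_ids[pp2.ravel()], "year": years[yy4.ravel()],
            "kind": kind, "consumption": prov_cons[:, ki, :].ravel(),
        }))
    prov_areas_df = pd.concat([
        pd.DataFrame({"province": prov_ids[pp.ravel()],
                      "year": years[yy3.ravel()],
                      "crop": np.array(NAMED_CROPS)[cc2.ravel()],
                      "area": prov_area[:, :len(NAMED_CROPS), :].ravel()}),
        pd.DataFrame({"province": prov_ids[pp2.ravel()],
                      "year": years[yy4.ravel()], "crop": TOTAL_AREA,
                      "area": prov_total_area.ravel()}),
    ], ignore_index=True)
    prov_totals = ProvincialTotals(
        consumption=pd.concat(prov_cons_rows, ignore_index=True),
        areas=prov_areas_df,
    ).validate()
    prov_rates_tbl = ProvincialRates(prov_rates_df).validate()

    # ---- county statistics with injected missingness --------------------
    miss = _missing_pattern(rng, n, ny, config.missing_rate, config.max_gap_run)
    miss_map = {(county_ids[j], years[y]): True
                for j, y in zip(*np.nonzero(miss))}

    def blank(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
        df = df.copy()
        key = list(zip(df["county"], df["year"]))
        is_missing = np.array([k in miss_map for k in key])
        df["status"] = np.where(is_missing, Status.MISSING, Status.OBSERVED)
        df.loc[is_missing, value_col] = np.nan
        return df

    county = CountyStats(
        provinces=pd.DataFrame({"county": county_ids,
                                "province": prov_ids[prov_of]}),
        consumption=blank(cons_long, "consumption"),
        areas=blank(truth_areas, "area"),
    ).validate()

    # ---- masks -----------------------------------------------------------
    masks: dict[tuple[str, int], np.ndarray] = {}
    for ci, crop in enumerate(ALL_CROPS[:len(NAMED_CROPS)]):
        for yi, year in enumerate(years):
            has = np.zeros(n + 1, dtype=bool)
            has[county_ids[area[:, ci, yi] > 0]] = True
            masks[(crop, int(year))] = has[raster]
    for yi, year in enumerate(years):
        has = np.zeros(n + 1, dtype=bool)
        has[county_ids[cropland[:, yi] > 0]] = True
        masks[(CROPLAND_AREA, int(year))] = has[raster]

    return World(config=config, truth=truth, prov_rates=prov_rates_tbl,
                 prov_totals=prov_totals, county=county,
                 county_raster=raster, crop_masks=masks, geom=geom)


PATHOLOGIES = ("overshoot_crops", "zero_area_county", "long_gap")


def perturb_world(world: World, inconsistency: str) -> World:
    """Inject exactly one named pathology; everything else unchanged."""
    if inconsistency not in PATHOLOGIES:
        raise CnpError(f"unknown pathology {inconsistency!r}; "
                       f"known: {PATHOLOGIES}")
    w = copy.deepcopy(world)
    years = w.config.year_list
    if inconsistency == "overshoot_crops":
        # inflate one named-crop provincial rate far past the total
        df = w.prov_rates.df
        mask = ((df["province"] == df["province"].iloc[0])
                & (df["year"] == years[0]) & (df["crop"] == "rice")
                & (df["kind"] == "phosphorus"))
        df.loc[mask, "rate"] *= 1e3
    elif inconsistency == "zero_area_county":
        county = w.county.provinces["county"].iloc[0]
        year = years[0]
        sel = (w.county.areas["county"] == county) & (w.county.areas["year"] == year)
        w.county.areas.loc[sel, "area"] = 0.0
        w.county.areas.loc[sel, "status"] = Status.OBSERVED
        csel = ((w.county.consumption["county"] == county)
                & (w.county.consumption["year"] == year))
        w.county.consumption.loc[csel, "consumption"] = (
            w.county.consumption.loc[csel, "consumption"].fillna(1.0).clip(lower=1.0))
        w.county.consumption.loc[csel, "status"] = Status.OBSERVED
    else:  # long_gap
        county = w.county.provinces["county"].iloc[0]
        run = w.config.max_gap_run + 2
        if len(years) < run + 2:
            raise CnpError("year span too short for a long gap")
        gap_years = years[1:1 + run]
        asel = (w.county.areas["county"] == county) & (
            w.county.areas["year"].isin(gap_years))
        w.county.areas.loc[asel, "area"] = np.nan
        w.county.areas.loc[asel, "status"] = Status.MISSING
        csel = (w.county.consumption["county"] == county) & (
            w.county.consumption["year"].isin(gap_years))
        w.county.consumption.loc[csel, "consumption"] = np.nan
        w.county.consumption.loc[csel, "status"] = Status.MISSING
    return w
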