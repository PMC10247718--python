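"""National summary statistics over the harmonized county tables.

Covers the validation-style analyses: area-weighted national annual
mean rates per crop, relative time trends (% per year) with a t-test on
the OLS slope, Tukey HSD contrasts between crops with a compact letter
display, the national total-consumption series, and the per-cropland
rate map (total P2O5 consumption over physical cropland area, which
multi-cropping makes distinct from summed sown area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .convert import CompositionWeights
from .errors import CnpError, InconsistentDataError
from .grid import GridGeometry, RateMap, rasterize_rates
from .tables import (
    CROPLAND_AREA,
    CountyRates,
    CountyStats,
    Kind,
    NAMED_CROPS,
    Status,
)


def national_series(
    rates: CountyRates,
    county: CountyStats,
    crops: str | list[str],
) -> pd.DataFrame:
    """Area-weighted national mean rate per year for one crop (or a
    group of sub-crop labels combined by area weighting).

    mean_y = sum_j FR_{i,j,y} A_{i,j,y} / sum_j A_{i,j,y} over counties
    with a defined rate.  Returns ``year, mean, area``.
    """
    if rates.p2o5 is None:
        raise CnpError("national_series needs a converted table (p2o5 set)")
    crops = [crops] if isinstance(crops, str) else list(crops)
    sel = rates.p2o5
    sel = sel[sel["crop"].isin(crops) & (sel["status"] != Status.DROPPED)
              & sel["p2o5_rate"].notna()]
    areas = county.areas[county.areas["crop"].isin(crops)][
        ["county", "year", "crop", "area"]]
    merged = sel.merge(areas, on=["county", "year", "crop"], how="inner")
    merged = merged[merged["area"].notna() & (merged["area"] > 0)]
    if merged.empty:
        raise CnpError(f"no defined rates for crops {crops}")
    merged["wx"] = merged["p2o5_rate"] * merged["area"]
    g = merged.groupby("year", sort=True)
    out = pd.DataFrame({"area": g["area"].sum(), "wx": g["wx"].sum()})
    if (out["area"] <= 0).any():
        raise CnpError("year with zero total growing area")
    out["mean"] = out["wx"] / out["area"]
    return out.reset_index()[["year", "mean", "area"]]


@dataclass
class TrendResult:
    """OLS trend of an annual series.

    ``relative_trend`` is 100 x slope / period mean (% per year);
    ``degenerate`` flags a zero-residual (perfect) fit, for which the
    t-test is not meaningful.
    """

    slope: float
    p_value: float
    period_mean: float
    relative_trend: float
    n_years: int
    degenerate: bool = False


def relative_trend(series: pd.DataFrame) -> TrendResult:
    """OLS of annual mean vs calendar year with a two-sided slope t-test."""
    if len(series) < 3:
        raise CnpError("trend needs at least 3 years")
    x = series["year"].to_numpy(dtype=float)
    y = series["mean"].to_numpy(dtype=float)
    res = sps.linregress(x, y)
    slope = float(res.slope)
    mean = float(np.mean(y))
    fitted = res.intercept + slope * x
    ssr = float(np.sum((y - fitted) ** 2))
    degenerate = ssr <= 1e-14 * max(1.0, float(np.sum(y**2)))
    if degenerate:
        p = 1.0 if abs(slope) < 1e-300 else 0.0
    else:
        p = float(res.pvalue)
    rel = 100.0 * slope / mean if mean != 0 else np.nan
    return TrendResult(slope=slope, p_value=p, period_mean=mean,
                       relative_trend=rel, n_years=len(series),
                       degenerate=degenerate)


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD p-values and a compact letter display."""

    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def _compact_letters(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.
    """
    # start with one letter set containing everything; split on each
    # significant pair that is still jointly covered
    sets: list[set[str]] = [set(groups)]
    for a, b in sorted(distinct):
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: (min(groups.index(g) for g in s)))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return letters


def tukey_hsd(series_by_crop: dict[str, pd.DataFrame], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference contrasts between crops.

    Groups are crops; replicates are the annual national means.  All
    crops must cover the same years (a balanced one-way layout).
    """
    if len(series_by_crop) < 2:
        raise CnpError("Tukey HSD needs at least 2 crops")
    years = None
    samples = {}
    for crop, ser in series_by_crop.items():
        yrs = tuple(ser["year"])
        if years is None:
            years = yrs
        elif yrs != years:
            raise CnpError("unequal year coverage across crops")
        samples[crop] = ser["mean"].to_numpy(dtype=float)
    names = list(samples)
    res = sps.tukey_hsd(*samples.values())
    p = pd.DataFrame(res.pvalue, index=names, columns=names)
    distinct = {(a, b) for i, a in enumerate(names) for j, b in enumerate(names)
                if i < j and p.iloc[i, j] < alpha}
    return TukeyResult(pairwise_p=p, letters=_compact_letters(names, distinct),
                       alpha=alpha)


def total_consumption_series(
    county: CountyStats, weights: CompositionWeights | None = None
) -> pd.Series:
    """National total P2O5 consumption per year (g), from county totals.

    sum_j [FC_phosphorus + FC_component x weighted content(year)] over
    counties with non-missing totals.
    """
    weights = weights or CompositionWeights.default()
    cons = county.consumption
    cons = cons[cons["consumption"].notna()]
    wide = cons.pivot_table(index=["county", "year"], columns="kind",
                            values="consumption", aggfunc="first")
    wide = wide.reindex(columns=[Kind.PHOSPHORUS.value, Kind.COMPONENT.value])
    wide = wide.fillna(0.0).reset_index()
    content = wide["year"].map(lambda y: weights.weighted_p2o5_content(y))
    wide["p2o5"] = wide[Kind.PHOSPHORUS.value] + wide[Kind.COMPONENT.value] * content
    out = wide.groupby("year", sort=True)["p2o5"].sum()
    out.name = "total_p2o5_g"
    return out


def county_p2o5_per_cropland(
    county: CountyStats, weights: CompositionWeights | None = None
) -> pd.DataFrame:
    """Total agricultural P2O5 rate per physical cropland, per county-year.

    Returns ``county, year, rate`` (g P2O5 / m2 cropland).  Requires
    ``cropland`` rows in the county area table.  Zero cropland with
    positive consumption raises.
    """
    weights = weights or CompositionWeights.default()
    cropland = county.areas[county.areas["crop"] == CROPLAND_AREA][
        ["county", "year", "area"]]
    if cropland.empty:
        raise CnpError("county area table has no cropland rows")
    cons = county.consumption[county.consumption["consumption"].notna()]
    wide = cons.pivot_table(index=["county", "year"], columns="kind",
                            values="consumption", aggfunc="first")
    wide = wide.reindex(columns=[Kind.PHOSPHORUS.value, Kind.COMPONENT.value])
    wide = wide.fillna(0.0).reset_index()
    content = wide["year"].map(lambda y: weights.weighted_p2o5_content(y))
    wide["p2o5"] = wide[Kind.PHOSPHORUS.value] + wide[Kind.COMPONENT.value] * content
    merged = wide.merge(cropland, on=["county", "year"], how="inner")
    bad = (merged["area"] <= 0) & (merged["p2o5"] > 0)
    if bad.any():
        raise InconsistentDataError(
            "positive consumption with zero cropland at "
            f"{merged.loc[bad, ['county', 'year']].head().to_dict('records')}")
    merged = merged[merged["area"] > 0]
    merged["rate"] = merged["p2o5"] / merged["area"]
    return merged[["county", "year", "rate"]]


def per_cropland_rate_map(
    county: CountyStats,
    county_raster: np.ndarray,
    cropland_mask: np.ndarray,
    geom: GridGeometry,
    year: int,
    weights: CompositionWeights | None = None,
) -> RateMap:
    """Rasterize the per-cropland total P2O5 rate for one year."""
    per_county = county_p2o5_per_cropland(county, weights)
    per_county = per_county[per_county["year"] == year]
    fake = pd.DataFrame({
        "county": per_county["county"], "year": year, "crop": "cropland",
        "p2o5_rate": per_county["rate"],
        "status": Status.OBSERVED, "reason": "",
    })
    table = CountyRates(
        df=fake.rename(columns={"p2o5_rate": "rate"}).assign(kind="phosphorus"),
        p2o5=fake,
    )
    return rasterize_rates(table, county_raster, cropland_mask, geom,
                           crop="cropland", year=year)
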