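"""County harmonization: gap-filling and the ratio allocation scheme.

The central idea: provincial crop-specific rates carry the *crop
structure* of fertilizer use, county totals carry the *local magnitude*.
For county j in province p, year y, crop i and one fertilizer kind:

    Rat_{i,j,y} = FR_{i,p,y} * A_{i,j,y} / sum_i FR_{i,p,y} * A_{i,j,y}
    FC_{i,j,y}  = Rat_{i,j,y} * FC_{j,y}
    FR_{i,j,y}  = FC_{i,j,y} / A_{i,j,y}

Because the ratios are normalized per county, the county total FC_{j,y}
is conserved exactly — the provincial rates only set the split between
crops.  When every county in a province shares the provincial rates and
the totals are consistent, the three equations collapse and the county
rates equal the provincial ones exactly.

Gap-filling: county statistical series have sporadic missing years.
Interior runs of at most ``max_run`` (default 2, i.e. "fewer than 3
consecutive years") missing years are filled with a natural cubic spline
through all observed points; longer runs and boundary gaps stay missing
and the affected county-years are dropped (with a reason code) rather
than guessed.  Filling is applied to the *inputs* (county total
consumption and areas); ratios and rates are then recomputed, which
preserves conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import InconsistentDataError, MissingDataError
from .tables import (
    Crop,
    CountyRates,
    CountyStats,
    KINDS,
    NAMED_CROPS,
    ProvincialRates,
    Status,
    TOTAL_AREA,
)


@dataclass(frozen=True)
class GapFillPolicy:
    """How missing years in county series are treated.

    ``max_run``: longest interior run of missing years that is filled
    (runs of ``max_run + 1`` or more stay missing).  ``extrapolate``:
    whether boundary gaps are filled (default no — splines are
    untrustworthy outside the observed span).  ``floor_at_zero``: clip
    filled values at 0, since negative mass/area is meaningless.
    """

    max_run: int = 2
    method: str = "cubic_spline"
    extrapolate: bool = False
    floor_at_zero: bool = True

    def __post_init__(self):
        if self.max_run < 0:
            raise ValueError("max_run must be >= 0")
        if self.method != "cubic_spline":
            raise ValueError(f"unknown gap-fill method {self.method!r}")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def gap_fill_series(
    years: np.ndarray, values: np.ndarray, policy: GapFillPolicy | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short interior gaps in an annual series with a natural spline.

    Parameters
    ----------
    years
        Consecutive integer years.
    values
        Float values with NaN marking missing years.

    Returns
    -------
    filled, status
        The filled value array and a per-year status array
        (``observed`` / ``gap_filled`` / ``missing``).
    """
    policy = policy or GapFillPolicy()
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    if len(years) != len(values):
        raise ValueError("years and values must have equal length")
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("series must be indexed by consecutive years")

    missing = np.isnan(values)
    status = np.where(missing, Status.MISSING, Status.OBSERVED).astype(object)
    filled = values.copy()
    if not missing.any():
        return filled, status

    obs_idx = np.flatnonzero(~missing)
    fillable = [
        (a, b)
        for a, b in _missing_runs(missing)
        if (b - a) <= policy.max_run
        and (policy.extrapolate or (a > 0 and b < len(values)))
        and not (a == 0 and b == len(values))
    ]
    if not fillable:
        return filled, status
    if len(obs_idx) < 4:
        raise MissingDataError(
            f"gap fill requested with only {len(obs_idx)} observed points (need >= 4)"
        )
    spline = CubicSpline(years[obs_idx], values[obs_idx], bc_type="natural",
                         extrapolate=policy.extrapolate)
    for a, b in fillable:
        est = spline(years[a:b])
        if policy.floor_at_zero:
            est = np.clip(est, 0.0, None)
        filled[a:b] = est
        status[a:b] = Status.GAP_FILLED
    return filled, status


def gap_fill_county_stats(
    county: CountyStats, policy: GapFillPolicy | None = None
) -> CountyStats:
    """Gap-fill every county consumption and area series.

    Series with fillable gaps but fewer than 4 observed points are left
    as-is (their missing years stay flagged).  Years absent from the
    table entirely are inserted as missing rows first, so run lengths
    are counted on the full year span of the dataset.
    """
    policy = policy or GapFillPolicy()
    years = np.arange(
        int(min(county.consumption["year"].min(), county.areas["year"].min())),
        int(max(county.consumption["year"].max(), county.areas["year"].max())) + 1,
    )

    def fill_frame(df: pd.DataFrame, keys: list[str], value_col: str) -> pd.DataFrame:
        # fast path: nothing missing and every series covers every year
        counts = df.groupby(keys, sort=False)["year"].size()
        if not df[value_col].isna().any() and (counts == len(years)).all():
            out = df.copy()
            out["status"] = Status.OBSERVED
            return out[keys + ["year", value_col, "status"]]
        out = []
        for key, grp in df.groupby(keys, sort=True):
            ser = grp.set_index("year")[value_col].reindex(years)
            try:
                filled, status = gap_fill_series(years, ser.to_numpy(), policy)
            except MissingDataError:
                filled = ser.to_numpy()
                status = np.where(np.isnan(filled), Status.MISSING,
                                  Status.OBSERVED).astype(object)
            sub = pd.DataFrame({"year": years, value_col: filled, "status": status})
            for k, v in zip(keys, key if isinstance(key, tuple) else (key,)):
                sub[k] = v
            out.append(sub)
        res = pd.concat(out, ignore_index=True)
        return res[keys + ["year", value_col, "status"]]

    cons = fill_frame(county.consumption, ["county", "kind"], "consumption")
    areas = fill_frame(county.areas, ["county", "crop"], "area")
    return CountyStats(county.provinces.copy(), cons, areas).validate()


def _county_crop_areas(county: CountyStats) -> pd.DataFrame:
    """Long area table over all four crop categories, with other = residual.

    Columns: county, year, crop, area, status.  The other-crops row
    inherits the total-area row's status; it is NaN whenever the total
    is missing.
    """
    named = county.areas[county.areas["crop"].isin(NAMED_CROPS)]
    total = county.areas[county.areas["crop"] == TOTAL_AREA]
    other = county.other_areas()
    other["crop"] = Crop.OTHER.value
    other = other.merge(total[["county", "year", "status"]], on=["county", "year"],
                        how="left")
    other.loc[other["area"].isna(), "status"] = Status.MISSING
    cols = ["county", "year", "crop", "area", "status"]
    return pd.concat([named[cols], other[cols]], ignore_index=True)


def allocation_ratios(
    prov_rates: ProvincialRates, county: CountyStats
) -> pd.DataFrame:
    """Per-county allocation ratios Rat_{i,j,y} for both fertilizer kinds.

    Returns ``county, year, crop, kind, ratio, status``.  Statuses:
    ``observed`` (clean), ``gap_filled`` (a filled area contributed),
    ``named_only`` (province had no other-crops rate; allocation over
    the three named crops), ``undefined`` (missing area or no fertilized
    area — ratio is NaN).
    """
    areas = _county_crop_areas(county)
    areas = areas.merge(county.provinces, on="county", validate="m:1")
    # cross the area table with the two kinds, then attach provincial rates
    frames = []
    for kind in KINDS:
        f = areas.copy()
        f["kind"] = kind
        frames.append(f)
    full = pd.concat(frames, ignore_index=True)
    rates = prov_rates.df[["province", "year", "crop", "kind", "rate"]]
    full = full.merge(rates, on=["province", "year", "crop", "kind"], how="left")

    named_no_rate = (full["crop"].isin(NAMED_CROPS) & full["rate"].isna()
                     & (full["area"] > 0))
    if named_no_rate.any():
        bad = full.loc[named_no_rate, ["province", "year", "crop", "kind"]]
        raise InconsistentDataError(
            "provincial rate missing for named crop with positive county area: "
            f"{bad.drop_duplicates().head().to_dict('records')}"
        )

    other_no_rate = (full["crop"] == Crop.OTHER.value) & full["rate"].isna()
    full["weight"] = (full["rate"].fillna(0.0) * full["area"]).where(~other_no_rate, 0.0)
    full["_area_na"] = full["area"].isna()
    full["_gap"] = full["status"] == Status.GAP_FILLED
    full["_fb"] = other_no_rate

    grp = full.groupby(["county", "year", "kind"], sort=False)
    area_missing = grp["_area_na"].transform("any").to_numpy()
    denom = grp["weight"].transform("sum")
    fallback = grp["_fb"].transform("any").to_numpy()
    gap = grp["_gap"].transform("any").to_numpy()

    undefined = area_missing | (denom <= 0).to_numpy()
    full["ratio"] = np.where(undefined, np.nan, full["weight"] / denom.where(denom > 0))
    full.loc[other_no_rate, "ratio"] = np.nan

    status = np.full(len(full), Status.OBSERVED, dtype=object)
    status[gap] = Status.GAP_FILLED
    status[fallback] = Status.NAMED_ONLY
    status[undefined | other_no_rate.to_numpy()] = Status.UNDEFINED
    full["status"] = status
    return full[["county", "year", "crop", "kind", "ratio", "status"]]


def allocate_consumption(
    ratios: pd.DataFrame, county: CountyStats
) -> pd.DataFrame:
    """FC_{i,j,y} = Rat_{i,j,y} x FC_{j,y}; conserves the county total.

    Returns ``county, year, crop, kind, consumption, status, reason``.
    """
    cons = county.consumption.rename(columns={"status": "cons_status",
                                              "consumption": "county_total"})
    out = ratios.merge(cons, on=["county", "year", "kind"], how="left")
    if out["cons_status"].isna().any():
        bad = out.loc[out["cons_status"].isna(),
                      ["county", "year", "kind"]].drop_duplicates()
        raise InconsistentDataError(
            f"ratio rows without a county total: {bad.head().to_dict('records')}"
        )
    cons_missing = out["cons_status"] == Status.MISSING
    ratio_undef = out["status"] == Status.UNDEFINED
    out["consumption"] = out["ratio"] * out["county_total"]

    status = out["status"].to_numpy(dtype=object).copy()
    reason = np.full(len(out), "", dtype=object)
    gap = (out["cons_status"] == Status.GAP_FILLED) & (status == Status.OBSERVED)
    status[np.asarray(gap)] = Status.GAP_FILLED
    status[np.asarray(ratio_undef)] = Status.DROPPED
    reason[np.asarray(ratio_undef)] = "undefined_ratio"
    status[np.asarray(cons_missing)] = Status.DROPPED
    reason[np.asarray(cons_missing)] = "missing_consumption"
    out.loc[cons_missing, "consumption"] = np.nan
    out["status"] = status
    out["reason"] = reason
    return out[["county", "year", "crop", "kind", "consumption", "status", "reason"]]


def county_rates(
    consumption: pd.DataFrame, county: CountyStats
) -> CountyRates:
    """FR_{i,j,y} = FC_{i,j,y} / A_{i,j,y}: the harmonized rate table.

    Zero area with zero allocated consumption yields no rate (dropped,
    reason ``zero_area``); zero area with positive consumption signals
    inconsistent upstream tables and raises.
    """
    areas = _county_crop_areas(county).rename(columns={"status": "area_status"})
    out = consumption.merge(areas, on=["county", "year", "crop"], how="left")
    if out["area"].isna().any() and (out["status"] != Status.DROPPED).any():
        miss = out["area"].isna() & (out["status"] != Status.DROPPED)
        if miss.any():
            out.loc[miss, "status"] = Status.DROPPED
            out.loc[miss, "reason"] = "missing_area"

    zero_area = out["area"].fillna(0.0) <= 0
    positive = out["consumption"].fillna(0.0) > 0
    if (zero_area & positive).any():
        bad = out.loc[zero_area & positive, ["county", "year", "crop", "kind"]]
        raise InconsistentDataError(
            f"positive consumption on zero growing area: "
            f"{bad.head().to_dict('records')}"
        )

    live = (out["status"] != Status.DROPPED) & ~zero_area
    out["rate"] = np.nan
    out.loc[live, "rate"] = out.loc[live, "consumption"] / out.loc[live, "area"]
    newly_dropped = (out["status"] != Status.DROPPED) & zero_area
    out.loc[newly_dropped, "status"] = Status.DROPPED
    out.loc[newly_dropped, "reason"] = "zero_area"
    gap_area = (out["area_status"] == Status.GAP_FILLED) & (
        out["status"] == Status.OBSERVED)
    out.loc[gap_area, "status"] = Status.GAP_FILLED
    df = out[["county", "year", "crop", "kind", "rate", "status", "reason"]].copy()
    return CountyRates(df).validate()


def harmonize(
    prov_rates: ProvincialRates,
    county: CountyStats,
    policy: GapFillPolicy | None = None,
) -> CountyRates:
    """Gap-fill then run the full three-step allocation."""
    filled = gap_fill_county_stats(county, policy)
    ratios = allocation_ratios(prov_rates, filled)
    cons = allocate_consumption(ratios, filled)
    return county_rates(cons, filled)
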