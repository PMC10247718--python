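"""End-to-end pipeline: statistics tables in, rate maps out.

Stage order: provincial residual rates -> gap-fill county series ->
ratio allocation -> per-kind county rates -> P2O5 summation ->
rasterization.  Each stage's flags (clamped, gap_filled, dropped, ...)
are preserved and summarized in the result's event log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .convert import CompositionWeights, total_p2o5_rate
from .grid import GridGeometry, RateMap, rasterize_rates, write_ratemap
from .harmonize import (
    GapFillPolicy,
    allocate_consumption,
    allocation_ratios,
    county_rates,
    gap_fill_county_stats,
)
from .provincial import other_crops_rate
from .tables import CountyRates, CountyStats, NAMED_CROPS, ProvincialRates, ProvincialTotals

logger = logging.getLogger("cnp")


@dataclass
class PipelineResult:
    """County rate tables plus bookkeeping from every stage."""

    rates: CountyRates
    ratios: pd.DataFrame
    provincial_events: pd.DataFrame
    filled_county: CountyStats
    flag_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    prov_rates: ProvincialRates,
    prov_totals: ProvincialTotals,
    county: CountyStats,
    policy: GapFillPolicy | None = None,
    weights: CompositionWeights | None = None,
) -> PipelineResult:
    """Run the full harmonization and conversion chain."""
    policy = policy or GapFillPolicy()
    weights = weights or CompositionWeights.default()

    stage1 = other_crops_rate(prov_rates, prov_totals)
    if len(stage1.events):
        logger.info("provincial stage: %d clamp/undefined events",
                    len(stage1.events))

    filled = gap_fill_county_stats(county, policy)
    ratios = allocation_ratios(stage1.rates, filled)
    cons = allocate_consumption(ratios, filled)
    per_kind = county_rates(cons, filled)
    converted = total_p2o5_rate(per_kind, weights)

    flag_counts = dict(converted.p2o5["status"].value_counts())
    flag_counts = {str(k): int(v) for k, v in flag_counts.items()}
    logger.info("pipeline flags: %s", flag_counts)
    return PipelineResult(rates=converted, ratios=ratios,
                          provincial_events=stage1.events,
                          filled_county=filled, flag_counts=flag_counts)


def grid_maps(
    result: PipelineResult,
    county_raster,
    crop_masks: dict[tuple[str, int], "object"],
    geom: GridGeometry,
    directory: str | Path | None = None,
    crops: tuple[str, ...] = NAMED_CROPS,
    years: list[int] | None = None,
) -> dict[tuple[str, int], RateMap]:
    """Rasterize (and optionally write) rate maps for the named crops."""
    avail_years = sorted(set(result.rates.p2o5["year"]))
    years = years or avail_years
    maps = {}
    for crop in crops:
        for year in years:
            mask = crop_masks.get((crop, int(year)))
            if mask is None:
                continue
            rm = rasterize_rates(result.rates, county_raster, mask, geom,
                                 crop, int(year))
            maps[(crop, int(year))] = rm
            if directory is not None:
                write_ratemap(rm, directory)
    return maps
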