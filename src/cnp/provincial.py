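"""Provincial stage: crop-specific consumption and the residual
other-crops rate.

Yearbooks report crop-specific fertilizer *rates* (for rice, wheat,
maize) but only *total* fertilizer consumption per province.  The named
crops' consumption is rate x sown area; whatever remains of the
provincial total is attributed to the residual "other crops" category
and divided by the residual sown area to yield an other-crops rate.

Edge policies (the source statistics do occasionally disagree):

* negative residual (named crops "consume" more than the total) — the
  other-crops consumption is clamped to zero and the record flagged
  ``clamped``; negative mass never propagates;
* zero other-crops area with a positive residual — no rate is emitted
  (``undefined``); downstream allocation treats the absent category as
  zero-weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InconsistentDataError
from .tables import (
    Crop,
    NAMED_CROPS,
    ProvincialRates,
    ProvincialTotals,
    Status,
)


def crop_consumption(
    rates: ProvincialRates, totals: ProvincialTotals
) -> pd.DataFrame:
    """Named-crop consumption per province-year-kind: rate x sown area.

    Returns a DataFrame ``province, year, crop, kind, consumption`` (g).
    Raises :class:`InconsistentDataError` if a rate record has no
    matching area.
    """
    named = rates.df[rates.df["crop"].isin(NAMED_CROPS)]
    merged = named.merge(
        totals.areas, on=["province", "year", "crop"], how="left", validate="m:1"
    )
    if merged["area"].isna().any():
        bad = merged.loc[merged["area"].isna(),
                         ["province", "year", "crop", "kind"]]
        raise InconsistentDataError(
            f"no sown area for rate records: {bad.head().to_dict('records')}"
        )
    merged["consumption"] = merged["rate"] * merged["area"]
    return merged[["province", "year", "crop", "kind", "consumption"]]


@dataclass
class ProvincialStageResult:
    """Rates for all four crop categories plus an event log.

    ``rates.df`` carries a ``status`` column: ``observed`` for input
    named-crop rates, ``derived`` for computed other-crops rates,
    ``clamped`` where a negative residual was floored at zero.
    ``events`` lists every clamp/undefined occurrence for auditing.
    """

    rates: ProvincialRates
    consumption: pd.DataFrame
    events: pd.DataFrame = field(default_factory=pd.DataFrame)


def other_crops_rate(
    rates: ProvincialRates, totals: ProvincialTotals
) -> ProvincialStageResult:
    """Derive the residual other-crops rate per province-year-kind.

    rate_other = max(0, total - sum named consumption) / area_other.
    """
    cons = crop_consumption(rates, totals)
    # fixed ascending crop order keeps the conservation check deterministic
    cons_sorted = cons.sort_values(["province", "year", "kind", "crop"],
                                   kind="mergesort")
    named_sum = (cons_sorted.groupby(["province", "year", "kind"], sort=True)
                 ["consumption"].sum().rename("named"))
    tot = totals.consumption.set_index(["province", "year", "kind"])["consumption"]
    missing_tot = named_sum.index.difference(tot.index)
    if len(missing_tot):
        raise InconsistentDataError(
            f"no provincial total for {list(missing_tot)[:5]}"
        )
    other_area = totals.other_area().set_index(["province", "year"])["area"]

    frame = named_sum.to_frame()
    frame["total"] = tot.reindex(frame.index)
    frame = frame.reset_index()
    frame["area_other"] = frame.set_index(["province", "year"]).index.map(other_area)
    residual = frame["total"] - frame["named"]
    clamped = residual < 0
    residual = residual.clip(lower=0.0)
    undefined = (frame["area_other"] <= 0) & (residual > 0)
    zero_area_zero_res = (frame["area_other"] <= 0) & (residual <= 0)

    frame["crop"] = Crop.OTHER.value
    frame["consumption"] = residual
    frame["rate"] = np.where(frame["area_other"] > 0,
                             residual / frame["area_other"].replace(0, np.nan), np.nan)
    frame["status"] = Status.DERIVED
    frame.loc[clamped, "status"] = Status.CLAMPED
    frame.loc[undefined | zero_area_zero_res, "status"] = Status.UNDEFINED

    events = frame.loc[clamped | undefined,
                       ["province", "year", "kind", "status"]].copy()
    keep = ~(undefined | zero_area_zero_res)
    other_rows = frame.loc[keep, ["province", "year", "crop", "kind", "rate",
                                  "status"]]

    base = rates.df.copy()
    if "status" not in base.columns:
        base["status"] = Status.OBSERVED
    out = pd.concat([base, other_rows], ignore_index=True)
    all_cons = pd.concat(
        [cons, frame[["province", "year", "crop", "kind", "consumption"]]],
        ignore_index=True,
    )
    return ProvincialStageResult(
        rates=ProvincialRates(out).validate(),
        consumption=all_cons,
        events=events.reset_index(drop=True),
    )
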