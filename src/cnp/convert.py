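"""P2O5 conversion.

Phosphorus-fertilizer statistics are already reported as P2O5 mass.
Component (compound, multi-nutrient) fertilizer is reported as gross
product mass and is converted with a year-specific weighted P2O5
content: imported product carries 60.0% P2O5, domestic product 30.8%,
and the import/domestic market split changes year to year.  The split
table for China 2004-2016 ships with the package as a constants CSV and
can be replaced for other countries or periods.

Elemental-P quantities convert to P2O5 by the molar mass ratio 142/62
(P2O5 is 141.94 g/mol and contains two P at 30.97 g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CnpError, SchemaError
from .tables import CountyRates, Kind, Status

#: g P2O5 per g elemental P
P2O5_PER_P = 142.0 / 62.0

#: P2O5 mass fraction of imported / domestic component fertilizer
CONTENT_IMPORTED = 0.600
CONTENT_DOMESTIC = 0.308


@dataclass
class CompositionWeights:
    """Year-specific import/domestic shares of component fertilizer.

    ``shares``: DataFrame ``year, imported_share, domestic_share`` with
    shares as fractions summing to 1.  The P2O5 contents default to the
    bundled constants but are overridable.
    """

    shares: pd.DataFrame
    content_imported: float = CONTENT_IMPORTED
    content_domestic: float = CONTENT_DOMESTIC

    def __post_init__(self):
        cols = ("year", "imported_share", "domestic_share")
        missing = [c for c in cols if c not in self.shares.columns]
        if missing:
            raise SchemaError(f"CompositionWeights: missing columns {missing}")
        s = self.shares["imported_share"] + self.shares["domestic_share"]
        if not np.allclose(s, 1.0, atol=1e-9):
            raise SchemaError("CompositionWeights: shares do not sum to 1")
        for c in ("imported_share", "domestic_share"):
            if ((self.shares[c] < 0) | (self.shares[c] > 1)).any():
                raise SchemaError(f"CompositionWeights: {c} outside [0, 1]")
        self._by_year = self.shares.set_index("year")

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "CompositionWeights":
        """Load a constants CSV with columns year, imported_pct, domestic_pct."""
        raw = pd.read_csv(path)
        df = pd.DataFrame({
            "year": raw["year"].astype(int),
            "imported_share": raw["imported_pct"] / 100.0,
            "domestic_share": raw["domestic_pct"] / 100.0,
        })
        return cls(df, **kw)

    @classmethod
    def default(cls, **kw) -> "CompositionWeights":
        """The bundled China 2004-2016 split table."""
        ref = resources.files("cnp.data") / "component_shares.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path, **kw)

    def weighted_p2o5_content(self, year: int) -> float:
        """Share-weighted P2O5 mass fraction of component fertilizer."""
        try:
            row = self._by_year.loc[int(year)]
        except KeyError:
            raise CnpError(f"no component-fertilizer shares for year {year}") from None
        return (row["imported_share"] * self.content_imported
                + row["domestic_share"] * self.content_domestic)

    def content_series(self, years) -> pd.Series:
        """Vectorized :meth:`weighted_p2o5_content` over an iterable of years."""
        return pd.Series([self.weighted_p2o5_content(y) for y in years],
                         index=pd.Index(years, name="year"))


def component_to_p2o5(amount, year: int, weights: CompositionWeights):
    """Grams of component-fertilizer product -> grams of P2O5."""
    amount = np.asarray(amount, dtype=float)
    if (amount < 0).any():
        raise ValueError("negative fertilizer amount")
    return amount * weights.weighted_p2o5_content(year)


def p_mass_to_p2o5(amount):
    """Grams of elemental P -> grams of P2O5 (x 142/62)."""
    amount = np.asarray(amount, dtype=float)
    if (amount < 0).any():
        raise ValueError("negative phosphorus mass")
    out = amount * P2O5_PER_P
    return float(out) if out.ndim == 0 else out


def total_p2o5_rate(
    rates: CountyRates, weights: CompositionWeights | None = None
) -> CountyRates:
    """Sum the two kinds into a single P2O5 rate per county-year-crop.

    p2o5 = phosphorus rate + component rate x weighted content(year).
    If one kind is dropped/missing the sum covers the available kind and
    is flagged ``partial``; if both are absent the record is dropped.
    """
    weights = weights or CompositionWeights.default()
    df = rates.df
    live = df[df["status"] != Status.DROPPED]
    wide = live.pivot_table(index=["county", "year", "crop"], columns="kind",
                            values="rate", aggfunc="first")
    wide = wide.reindex(columns=[Kind.PHOSPHORUS.value, Kind.COMPONENT.value])
    wide = wide.reset_index()
    content = wide["year"].map(lambda y: weights.weighted_p2o5_content(y))
    p = wide[Kind.PHOSPHORUS.value]
    c = wide[Kind.COMPONENT.value] * content
    both_na = p.isna() & c.isna()
    p2o5 = p.fillna(0.0) + c.fillna(0.0)

    status = np.full(len(wide), Status.OBSERVED, dtype=object)
    gap_keys = set(map(tuple, live.loc[live["status"] == Status.GAP_FILLED,
                                       ["county", "year", "crop"]].to_numpy()))
    if gap_keys:
        keyarr = list(map(tuple, wide[["county", "year", "crop"]].to_numpy()))
        status[[k in gap_keys for k in keyarr]] = Status.GAP_FILLED
    partial = (p.isna() ^ c.isna())
    status[partial.to_numpy()] = Status.PARTIAL
    reason = np.full(len(wide), "", dtype=object)
    status[both_na.to_numpy()] = Status.DROPPED
    reason[both_na.to_numpy()] = "both_kinds_missing"
    p2o5 = p2o5.where(~both_na)

    out = pd.DataFrame({
        "county": wide["county"], "year": wide["year"], "crop": wide["crop"],
        "p2o5_rate": p2o5, "status": status, "reason": reason,
    })
    # county-year-crops dropped for *both* kinds upstream never reach the
    # pivot; re-add them so the table keeps one row per key with a reason
    dropped = df[df["status"] == Status.DROPPED]
    if len(dropped):
        done = set(map(tuple, out[["county", "year", "crop"]].to_numpy()))
        extra = dropped[["county", "year", "crop", "reason"]].drop_duplicates(
            subset=["county", "year", "crop"])
        extra = extra[[tuple(r) not in done
                       for r in extra[["county", "year", "crop"]].to_numpy()]]
        if len(extra):
            extra = extra.assign(p2o5_rate=np.nan, status=Status.DROPPED)
            out = pd.concat([out, extra[out.columns]], ignore_index=True)
    return CountyRates(rates.df.copy(), out).validate()
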