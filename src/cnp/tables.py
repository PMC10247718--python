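"""Domain types for the fertilizer-statistics tables.

The pipeline's vocabulary: two fertilizer *kinds* (phosphorus fertilizer,
whose statistics are already P2O5 mass, and multi-nutrient "component"
fertilizer, which needs a content conversion) and four *crop* categories
(rice, wheat, maize, and the residual "other").

Tables are thin dataclass wrappers around long-format pandas DataFrames
with documented schemas; every wrapper has a ``validate()`` raising
:class:`~cnp.errors.SchemaError` on violation.  Missing data is an
explicit status, never NaN-as-zero: the gap-filling rule needs to know
how long a run of absent years is.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError


class Kind(str, enum.Enum):
    """Fertilizer kind carried by every rate/consumption record."""

    PHOSPHORUS = "phosphorus"
    COMPONENT = "component"


class Crop(str, enum.Enum):
    """Crop category; ``OTHER`` is always the residual."""

    RICE = "rice"
    WHEAT = "wheat"
    MAIZE = "maize"
    OTHER = "other"


#: named (mapped) crops, in the fixed enumeration order used for all
#: conservation-sensitive summations
NAMED_CROPS: tuple[str, ...] = (Crop.RICE.value, Crop.WHEAT.value, Crop.MAIZE.value)
ALL_CROPS: tuple[str, ...] = NAMED_CROPS + (Crop.OTHER.value,)
KINDS: tuple[str, ...] = (Kind.PHOSPHORUS.value, Kind.COMPONENT.value)

#: label used in area tables for the total sown area row
TOTAL_AREA = "total"
#: label used in area tables for physical cropland area (multi-cropping
#: means total sown area may exceed it); optional, used by the
#: per-cropland validation analyses only
CROPLAND_AREA = "cropland"


class Status:
    """Provenance flags attached to records as they move through stages."""

    OBSERVED = "observed"
    MISSING = "missing"
    GAP_FILLED = "gap_filled"
    DERIVED = "derived"
    CLAMPED = "clamped"
    UNDEFINED = "undefined"
    DROPPED = "dropped"
    PARTIAL = "partial"
    NAMED_ONLY = "named_only"


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _require_unique(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise SchemaError(
            f"{what}: duplicate key rows for {keys}: "
            f"{df.loc[dup, keys].head().to_dict('records')}"
        )


def _require_nonneg(df: pd.DataFrame, col: str, what: str) -> None:
    bad = df[col].dropna() < 0
    if bad.any():
        raise SchemaError(f"{what}: negative values in {col!r}")


@dataclass
class ProvincialRates:
    """Crop-specific fertilizer rate per province-year, per kind.

    Schema: ``province, year, crop, kind, rate`` (g/m2), optional
    ``status``.  Input tables carry the named crops only; the residual
    other-crops rate is appended by the provincial stage.
    """

    df: pd.DataFrame

    COLUMNS = ("province", "year", "crop", "kind", "rate")

    def validate(self) -> "ProvincialRates":
        _require_columns(self.df, self.COLUMNS, "ProvincialRates")
        _require_unique(self.df, ["province", "year", "crop", "kind"], "ProvincialRates")
        _require_nonneg(self.df, "rate", "ProvincialRates")
        bad_kind = set(self.df["kind"]) - set(KINDS)
        if bad_kind:
            raise SchemaError(f"ProvincialRates: unknown kinds {bad_kind}")
        bad_crop = set(self.df["crop"]) - set(ALL_CROPS)
        if bad_crop:
            raise SchemaError(f"ProvincialRates: unknown crops {bad_crop}")
        return self


@dataclass
class ProvincialTotals:
    """Provincial totals: fertilizer consumption and sown areas.

    ``consumption``: ``province, year, kind, consumption`` (g).
    ``areas``: ``province, year, crop, area`` (m2) where ``crop`` runs
    over the named crops plus ``"total"`` (total sown area); the
    other-crops area is the residual total minus named.
    """

    consumption: pd.DataFrame
    areas: pd.DataFrame

    def validate(self) -> "ProvincialTotals":
        _require_columns(
            self.consumption, ("province", "year", "kind", "consumption"),
            "ProvincialTotals.consumption",
        )
        _require_unique(self.consumption, ["province", "year", "kind"],
                        "ProvincialTotals.consumption")
        _require_nonneg(self.consumption, "consumption", "ProvincialTotals.consumption")
        _require_columns(self.areas, ("province", "year", "crop", "area"),
                         "ProvincialTotals.areas")
        _require_unique(self.areas, ["province", "year", "crop"],
                        "ProvincialTotals.areas")
        _require_nonneg(self.areas, "area", "ProvincialTotals.areas")
        # named-crop areas may not exceed the total sown area
        wide = self.areas.pivot_table(index=["province", "year"], columns="crop",
                                      values="area", aggfunc="first")
        if TOTAL_AREA in wide.columns:
            named = [c for c in NAMED_CROPS if c in wide.columns]
            over = wide[named].sum(axis=1) > wide[TOTAL_AREA] * (1 + 1e-9)
            if over.any():
                raise SchemaError(
                    "ProvincialTotals.areas: named-crop areas exceed total sown "
                    f"area at {list(wide.index[over])[:5]}"
                )
        return self

    def other_area(self) -> pd.DataFrame:
        """Residual other-crops area per province-year (floored at 0)."""
        wide = self.areas.pivot_table(index=["province", "year"], columns="crop",
                                      values="area", aggfunc="first")
        named = wide.reindex(columns=list(NAMED_CROPS)).fillna(0.0)
        other = (wide[TOTAL_AREA] - named.sum(axis=1)).clip(lower=0.0)
        return other.rename("area").reset_index()


@dataclass
class CountyStats:
    """County totals with explicit missing-data status.

    ``provinces``: ``county, province`` — one row per county.
    ``consumption``: ``county, year, kind, consumption, status`` (g;
    value NaN exactly when status is missing/dropped).
    ``areas``: ``county, year, crop, area, status`` (m2) with ``crop``
    over named crops plus ``"total"`` (and optionally ``"cropland"``).
    """

    provinces: pd.DataFrame
    consumption: pd.DataFrame
    areas: pd.DataFrame

    def validate(self) -> "CountyStats":
        _require_columns(self.provinces, ("county", "province"), "CountyStats.provinces")
        _require_unique(self.provinces, ["county"], "CountyStats.provinces")
        _require_columns(self.consumption,
                         ("county", "year", "kind", "consumption", "status"),
                         "CountyStats.consumption")
        _require_unique(self.consumption, ["county", "year", "kind"],
                        "CountyStats.consumption")
        _require_nonneg(self.consumption, "consumption", "CountyStats.consumption")
        _require_columns(self.areas, ("county", "year", "crop", "area", "status"),
                         "CountyStats.areas")
        _require_unique(self.areas, ["county", "year", "crop"], "CountyStats.areas")
        _require_nonneg(self.areas, "area", "CountyStats.areas")
        known = set(self.provinces["county"])
        for name, df in (("consumption", self.consumption), ("areas", self.areas)):
            orphans = set(df["county"]) - known
            if orphans:
                raise SchemaError(
                    f"CountyStats.{name}: counties without a province mapping: "
                    f"{sorted(orphans)[:5]}"
                )
        for name, df, col in (("consumption", self.consumption, "consumption"),
                              ("areas", self.areas, "area")):
            absent = df["status"].isin([Status.MISSING, Status.DROPPED])
            if (df.loc[absent, col].notna()).any():
                raise SchemaError(f"CountyStats.{name}: missing record carries a value")
            if (df.loc[~absent, col].isna()).any():
                raise SchemaError(f"CountyStats.{name}: present record without a value")
        return self

    def other_areas(self) -> pd.DataFrame:
        """Residual other-crops area per county-year, floored at 0.

        NaN where the total or any named area is absent.
        """
        wide = self.areas.pivot_table(index=["county", "year"], columns="crop",
                                      values="area", aggfunc="first")
        named = wide.reindex(columns=list(NAMED_CROPS)).fillna(0.0)
        # a county that never reports a named crop grows none of it; but a
        # county-year flagged missing has NaN total and stays NaN
        other = (wide.get(TOTAL_AREA) - named.sum(axis=1)).clip(lower=0.0)
        return other.rename("area").reset_index()


@dataclass
class CountyRates:
    """Harmonized county-level crop-specific rates.

    ``df``: ``county, year, crop, kind, rate, status, reason`` (g/m2 of
    the kind's own reporting basis).  ``p2o5`` (set by the conversion
    stage): ``county, year, crop, p2o5_rate, status, reason`` in
    g P2O5 / m2.
    """

    df: pd.DataFrame
    p2o5: pd.DataFrame | None = None

    def validate(self) -> "CountyRates":
        _require_columns(self.df, ("county", "year", "crop", "kind", "rate",
                                   "status", "reason"), "CountyRates")
        _require_unique(self.df, ["county", "year", "crop", "kind"], "CountyRates")
        _require_nonneg(self.df, "rate", "CountyRates")
        dropped = self.df["status"] == Status.DROPPED
        if (self.df.loc[dropped, "reason"] == "").any():
            raise SchemaError("CountyRates: dropped record without a reason code")
        if self.p2o5 is not None:
            _require_columns(self.p2o5, ("county", "year", "crop", "p2o5_rate",
                                         "status", "reason"), "CountyRates.p2o5")
            _require_unique(self.p2o5, ["county", "year", "crop"], "CountyRates.p2o5")
            _require_nonneg(self.p2o5, "p2o5_rate", "CountyRates.p2o5")
        return self


def empty_status(n: int) -> np.ndarray:
    return np.full(n, Status.OBSERVED, dtype=object)
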