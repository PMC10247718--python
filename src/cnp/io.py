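"""CSV readers and writers for the statistics tables.

Interchange format is long-form CSV (UTF-8, header row, RFC-4180):

* ``provincial_rates.csv``        — province, year, crop, kind, rate
* ``provincial_consumption.csv``  — province, year, kind, consumption
* ``provincial_areas.csv``        — province, year, crop, area
* ``county_provinces.csv``        — county, province
* ``county_consumption.csv``      — county, year, kind, consumption
* ``county_areas.csv``            — county, year, crop, area

Empty value cells in the county files mean *missing* — the record is
flagged, never silently zero.  All values are converted to canonical
units (g, m2, g/m2) on read, driven by a :class:`~cnp.units.UnitConfig`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import SchemaError
from .tables import CountyRates, CountyStats, ProvincialRates, ProvincialTotals, Status
from .units import UnitConfig

#: the file-set keys expected by :func:`read_statistics`
STATISTICS_FILES = (
    "provincial_rates",
    "provincial_consumption",
    "provincial_areas",
    "county_provinces",
    "county_consumption",
    "county_areas",
)


def _read(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _flag_missing(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    df = df.copy()
    df["status"] = Status.OBSERVED
    df.loc[df[value_col].isna(), "status"] = Status.MISSING
    return df


def read_statistics(
    paths: Mapping[str, str | Path], units: UnitConfig | None = None
) -> tuple[ProvincialRates, ProvincialTotals, CountyStats]:
    """Read the full statistics file set into validated canonical tables.

    Parameters
    ----------
    paths
        Mapping from the keys in :data:`STATISTICS_FILES` to file paths.
    units
        Input units; defaults to canonical (g, m2, g/m2).
    """
    units = units or UnitConfig()
    missing = [k for k in STATISTICS_FILES if k not in paths]
    if missing:
        raise SchemaError(f"read_statistics: missing file-set entries {missing}")

    pr = _read(paths["provincial_rates"], ("province", "year", "crop", "kind", "rate"))
    pr["rate"] = units.rate_to_canonical(pr["rate"])

    pc = _read(paths["provincial_consumption"],
               ("province", "year", "kind", "consumption"))
    pc["consumption"] = units.mass_to_canonical(pc["consumption"])

    pa = _read(paths["provincial_areas"], ("province", "year", "crop", "area"))
    pa["area"] = units.area_to_canonical(pa["area"])

    cp = _read(paths["county_provinces"], ("county", "province"))

    cc = _read(paths["county_consumption"], ("county", "year", "kind", "consumption"))
    cc["consumption"] = units.mass_to_canonical(cc["consumption"])
    cc = _flag_missing(cc, "consumption")

    ca = _read(paths["county_areas"], ("county", "year", "crop", "area"))
    ca["area"] = units.area_to_canonical(ca["area"])
    ca = _flag_missing(ca, "area")

    rates = ProvincialRates(pr).validate()
    totals = ProvincialTotals(pc, pa).validate()
    county = CountyStats(cp, cc, ca).validate()
    return rates, totals, county


def write_statistics(
    directory: str | Path,
    rates: ProvincialRates,
    totals: ProvincialTotals,
    county: CountyStats,
) -> dict[str, Path]:
    """Write the file set (canonical units) and return the path mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / f"{k}.csv" for k in STATISTICS_FILES}
    rates.df.to_csv(paths["provincial_rates"], index=False)
    totals.consumption.to_csv(paths["provincial_consumption"], index=False)
    totals.areas.to_csv(paths["provincial_areas"], index=False)
    county.provinces.to_csv(paths["county_provinces"], index=False)
    county.consumption.drop(columns="status").to_csv(
        paths["county_consumption"], index=False)
    county.areas.drop(columns="status").to_csv(paths["county_areas"], index=False)
    return paths


def write_county_rates(table: CountyRates, path: str | Path) -> Path:
    """Write a harmonized county-rate table, provenance flags included.

    The round trip through :func:`read_county_rates` is bit-exact:
    floats are serialized with shortest round-trip repr.
    """
    table.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    if table.p2o5 is not None:
        table.p2o5.to_csv(path.with_suffix(".p2o5.csv"), index=False)
    return path


def read_county_rates(path: str | Path) -> CountyRates:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False,
                     na_values={"rate": [""]}, dtype={"reason": str})
    p2o5 = None
    side = path.with_suffix(".p2o5.csv")
    if side.exists():
        p2o5 = pd.read_csv(side, keep_default_na=False,
                           na_values={"p2o5_rate": [""]}, dtype={"reason": str})
    return CountyRates(df, p2o5).validate()
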