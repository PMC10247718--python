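"""Unit handling.

Everything inside the package is expressed in canonical units:

* mass        — grams (g)
* area        — square metres (m2)
* rate        — grams per square metre (g/m2)

Yearbook-style inputs commonly arrive in kg/ha (rates), tonnes (masses)
and hectares or thousand-hectares (areas); conversion happens once, on
read, driven by an explicit :class:`UnitConfig`.  1 kg/ha = 0.1 g/m2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitError

# multiplicative factors to the canonical unit
MASS_FACTORS: dict[str, float] = {
    "g": 1.0,
    "kg": 1e3,
    "t": 1e6,
    "kt": 1e9,
}

AREA_FACTORS: dict[str, float] = {
    "m2": 1.0,
    "ha": 1e4,
    "kha": 1e7,
    "km2": 1e6,
}

RATE_FACTORS: dict[str, float] = {
    "g_per_m2": 1.0,
    "kg_per_ha": 0.1,
}


def _factor(table: dict[str, float], label: str, domain: str) -> float:
    try:
        return table[label]
    except KeyError:
        raise UnitError(
            f"unknown {domain} unit {label!r}; known: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class UnitConfig:
    """Input units for the three physical quantities of the CSV schema."""

    rate_unit: str = "g_per_m2"
    mass_unit: str = "g"
    area_unit: str = "m2"

    def rate_to_canonical(self, value):
        return value * _factor(RATE_FACTORS, self.rate_unit, "rate")

    def mass_to_canonical(self, value):
        return value * _factor(MASS_FACTORS, self.mass_unit, "mass")

    def area_to_canonical(self, value):
        return value * _factor(AREA_FACTORS, self.area_unit, "area")

    def rate_from_canonical(self, value):
        return value / _factor(RATE_FACTORS, self.rate_unit, "rate")

    def mass_from_canonical(self, value):
        return value / _factor(MASS_FACTORS, self.mass_unit, "mass")

    def area_from_canonical(self, value):
        return value / _factor(AREA_FACTORS, self.area_unit, "area")
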