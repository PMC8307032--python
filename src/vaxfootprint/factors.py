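"""Emission-factor registry and cold-chain physics.

The registry is the single source of unit conversions for the footprint
ledger: production factors (kg CO2e per kg of good), electricity factors
(per kWh), transport factors (per 1000 km and kg of payload, per vehicle-km,
per tonne-km, per person-km) and per-day cold-storage footprints.  Defaults
follow widely used life-cycle figures for Germany around 2019-2021.  Every
factor carries a relative uncertainty and a free-text source tag, and
round-trips through JSON unchanged.

Cold-chain physics helpers cover the sensible-heat energy of cooling a
payload (``Q = m cp dT``), the climate-impact weighting of air freight by a
radiative forcing index, and dry-ice sublimation losses in passive shipping
containers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import DomainError, FactorLookupError

__all__ = [
    "BASES",
    "EmissionFactor",
    "FactorRegistry",
    "ThermalQuery",
    "default_registry",
    "get_factor",
    "cooling_energy",
    "air_freight_factor",
    "dry_ice_sublimation",
    "CP_WATER",
    "CP_ICE",
    "CP_GLASS",
]

#: Accepted unit bases for a factor value.
BASES = frozenset(
    {
        "per_kg_product",   # kg CO2e per kg of manufactured good
        "per_1000km_kg",    # kg CO2e per 1000 km and kg of payload
        "per_vehicle_km",   # kg CO2e per km driven by one vehicle
        "per_tkm",          # kg CO2e per tonne-kilometre of freight
        "per_kWh",          # kg CO2e per kWh of electrical energy
        "per_day",          # kg CO2e per day of appliance operation
        "per_km_person",    # kg CO2e per km travelled by one person
    }
)

# Specific heat capacities, J kg^-1 K^-1
CP_WATER = 4186.0
CP_ICE = 2060.0
CP_GLASS = 703.0

J_PER_WH = 3600.0
WH_PER_KWH = 1000.0


@dataclass(frozen=True)
class EmissionFactor:
    """A named conversion from an activity unit to kg CO2 equivalents.

    Parameters
    ----------
    name
        Unique identifier within a registry.
    value
        kg CO2e per unit of ``basis``; must be non-negative.
    basis
        One of :data:`BASES`.
    rel_uncertainty
        Relative (fractional) uncertainty of ``value``, >= 0.
    source
        Free-text citation tag.
    metadata
        Optional extras such as printed range bounds or plausibility flags.
    """

    name: str
    value: float
    basis: str
    rel_uncertainty: float = 0.0
    source: str = ""
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise DomainError(f"unknown basis {self.basis!r}; expected one of {sorted(BASES)}")
        if self.value < 0:
            raise DomainError(f"factor {self.name!r}: value must be >= 0, got {self.value}")
        if self.rel_uncertainty < 0:
            raise DomainError(
                f"factor {self.name!r}: rel_uncertainty must be >= 0, got {self.rel_uncertainty}"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "value": self.value,
            "basis": self.basis,
            "rel_uncertainty": self.rel_uncertainty,
            "source": self.source,
        }
        if self.metadata:
            d["metadata"] = dict(self.metadata)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EmissionFactor":
        return cls(
            name=d["name"],
            value=float(d["value"]),
            basis=d["basis"],
            rel_uncertainty=float(d.get("rel_uncertainty", 0.0)),
            source=d.get("source", ""),
            metadata=dict(d.get("metadata", {})),
        )


class FactorRegistry(Mapping[str, EmissionFactor]):
    """Name-indexed collection of :class:`EmissionFactor` objects.

    Behaves like a read-mostly mapping; :meth:`add` refuses duplicate names
    unless ``replace=True``.
    """

    def __init__(self, factors: Iterator[EmissionFactor] = ()):  # type: ignore[assignment]
        self._factors: dict[str, EmissionFactor] = {}
        for f in factors:
            self.add(f)

    def add(self, factor: EmissionFactor, replace: bool = False) -> None:
        if factor.name in self._factors and not replace:
            raise DomainError(f"factor {factor.name!r} already registered")
        self._factors[factor.name] = factor

    def get_factor(self, name: str) -> EmissionFactor:
        try:
            return self._factors[name]
        except KeyError:
            raise FactorLookupError(name, self._factors) from None

    def value(self, name: str) -> float:
        return self.get_factor(name).value

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> EmissionFactor:
        return self.get_factor(name)

    def __iter__(self):
        return iter(self._factors)

    def __len__(self) -> int:
        return len(self._factors)

    # Serialization --------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps([f.to_dict() for f in self._factors.values()], indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FactorRegistry":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(EmissionFactor.from_dict(d) for d in json.loads(text))


def get_factor(registry: FactorRegistry, name: str) -> EmissionFactor:
    """Module-level convenience wrapper around :meth:`FactorRegistry.get_factor`."""
    return registry.get_factor(name)


def default_registry() -> FactorRegistry:
    """Registry pre-loaded with the package's reference emission factors.

    Production factors are cradle-to-gate kg CO2e per kg of good; the two
    electricity factors distinguish the 2019 German grid mix from a generic
    primary-energy figure.  Transport factors are payload-based; the
    RFI-weighted air-freight factor applies a radiative forcing index of
    ~3.4 (within the accepted 3-4 band for long-haul flight) to the fuel-only
    base factor.  Where the literature prints a range, the registry stores the
    value used by the reference scenarios and keeps the range as metadata.
    """
    F = EmissionFactor
    return FactorRegistry(
        [
            F("electricity_generic", 0.502, "per_kWh", 0.10, "primary energy production"),
            F("german_grid", 0.401, "per_kWh", 0.10, "German electricity mix 2019"),
            F("dry_ice", 0.15, "per_kg_product", 0.03, "dry ice manufacture",
              {"kWh_per_kg": 0.36}),
            F("gas_liquefaction", 0.14, "per_kg_product", 0.10, "natural gas liquefaction",
              {"kWh_per_kg": 0.35}),
            F("glass", 0.72, "per_kg_product", 0.05, "container glass manufacture",
              {"kWh_per_kg": 2.73}),
            F("paper", 0.61, "per_kg_product", 0.05, "paper and cardboard"),
            F("polypropylene", 1.5, "per_kg_product", 0.05, "medical-grade polypropylene"),
            F("sterilization", 0.77, "per_kg_product", 0.05, "syringe sterilization energy"),
            F("pet_virgin", 3.71, "per_kg_product", 0.10, "PET cradle-to-grave, no recycling"),
            F("pet_recycled", 1.54, "per_kg_product", 0.10, "PET cradle-to-grave with recycling"),
            F("steam", 136.0, "per_kg_product", 1.0, "process steam",
              {"suspect": True,
               "note": "three orders of magnitude above comparable goods; kept as printed "
                       "in the source compilation but not used by any built-in scenario"}),
            F("refrigerator_production", 322.0, "per_kg_product", 0.20,
              "production of one large refrigerator (per appliance, not per kg)"),
            F("mrna_process", 500.0, "per_kg_product", 5.0,
              "biochemical mRNA synthesis, order-of-magnitude placeholder"),
            # Transport ----------------------------------------------------
            F("air_freight_base", 0.67, "per_1000km_kg", 0.50, "air cargo, fuel CO2 only"),
            F("air_freight_rfi", 2.3, "per_1000km_kg", 0.50,
              "air cargo weighted by radiative forcing index",
              {"rfi": 2.3 / 0.67, "rfi_range": [3.0, 4.0]}),
            F("truck_payload", 0.2, "per_1000km_kg", 0.20, "road freight payload",
              {"range": [0.11, 0.23]}),
            F("car", 0.2, "per_vehicle_km", 0.20, "passenger car, internal combustion"),
            F("patient_travel", 0.1, "per_km_person", 1.0, "patient trip to vaccination site"),
            F("freight_tkm", 0.1, "per_tkm", 0.20, "distribution truck, payload-shared"),
            F("vehicle_km", 0.3, "per_vehicle_km", 0.20, "distribution truck, whole vehicle"),
            # Cold storage -------------------------------------------------
            F("freezer_600l", 8.0, "per_day", 0.10, "-80 degC freezer, 600-700 L",
              {"kg_per_day_range": [7.0, 9.0]}),
            F("freezer_stationary_159l", 2.7, "per_day", 0.10, "stationary -20..-80 degC, 159 L"),
            F("freezer_portable_11l", 1.2, "per_day", 0.10, "portable -20..-80 degC, 11 L"),
            F("freezer_inefficient_50l", 8.0, "per_day", 0.10, "inefficient -70 degC, 50 L"),
            F("refrigerator_daily", 0.1, "per_day", 0.20, "average refrigerator, per day"),
            # Waste --------------------------------------------------------
            F("plastics_combustion_gross", 2.41, "per_kg_product", 0.20,
              "municipal incineration of mixed plastics"),
            F("plastics_combustion_credit", 0.65, "per_kg_product", 0.20,
              "energy-recovery credit of incineration"),
            F("glass_recycling_credit", 0.4, "per_kg_product", 0.20, "glass recycling credit"),
            F("paper_recycling_credit", 0.064, "per_kg_product", 0.20, "paper recycling credit"),
        ]
    )


@dataclass(frozen=True)
class ThermalQuery:
    """Inputs of a sensible-heat calculation ``Q = m cp dT``.

    ``delta_t`` may have either sign (cooling or heating); the energy uses
    its magnitude.
    """

    mass_kg: float
    cp: float  # J kg^-1 K^-1
    delta_t: float  # K

    def __post_init__(self) -> None:
        if self.mass_kg < 0:
            raise DomainError(f"mass must be >= 0, got {self.mass_kg}")
        if self.cp <= 0:
            raise DomainError(f"cp must be > 0, got {self.cp}")


def cooling_energy(q: ThermalQuery) -> float:
    """Sensible-heat energy in Wh to change a payload's temperature.

    Returns ``m * cp * |dT| / 3600``.  Cooling 1 kg of water from 20 to 0 degC
    takes about 23 Wh; cooling 1 kg of ice from 0 to -70 degC about 40 Wh.
    Latent heat of fusion is out of scope (the reference figures exclude it).
    """
    return q.mass_kg * q.cp * abs(q.delta_t) / J_PER_WH


def air_freight_factor(base: float, rfi: float) -> float:
    """Weight a payload air-freight factor by a radiative forcing index.

    The RFI (>= 1, typically 3-4 for long-haul flights above ~9 km) converts
    fuel-only CO2 into climate-impact-equivalent CO2, accounting for
    contrails, NOx and particulates at altitude.
    """
    if base < 0:
        raise DomainError(f"base factor must be >= 0, got {base}")
    if rfi < 1:
        raise DomainError(f"RFI must be >= 1, got {rfi}")
    return base * rfi


def dry_ice_sublimation(
    volume_l: float,
    rate_g_per_h_l: float,
    duration_h: float,
    max_rate: float = 10.0,
) -> float:
    """Mass of dry ice (kg) lost to sublimation in a passive container.

    Commercial vacuum-insulated boxes lose roughly 1.4-5 g of dry ice per
    hour and litre of volume; rates outside ``[0, max_rate]`` are rejected as
    implausible.
    """
    if volume_l < 0 or rate_g_per_h_l < 0 or duration_h < 0:
        raise DomainError("volume, rate and duration must all be >= 0")
    if rate_g_per_h_l > max_rate:
        raise DomainError(
            f"sublimation rate {rate_g_per_h_l} g/(h L) outside plausibility band [0, {max_rate}]"
        )
    return volume_l * rate_g_per_h_l * duration_h / 1000.0
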