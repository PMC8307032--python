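"""Packaging arithmetic for vaccine presentations.

A :class:`ShipmentSpec` captures how one shipping unit of a vaccine
presentation translates into doses, mass and liquid volume, so that any
order size can be scaled to the mass and volume inputs of the footprint
ledger.  Two built-in presentations are provided:

``BNT162b2``
    One carton of 975 six-dose vials (5850 doses) weighing 36 kg, shipped in
    a thermal container holding a 23 kg dry-ice charge that is refreshed once
    in transit.  The dry ice and the 3 kg container packaging travel with the
    carton but are accounted in the ledger's dedicated dry-ice line, not in
    the shipped payload mass, which keeps the payload arithmetic free of
    double counting (1e6 doses -> ~6154 kg).

``mRNA-1273``
    One pallet of 8 containers totalling 115,200 ten-dose vials' worth of
    doses at 290 kg and 54 L of vaccine liquid; no dry ice
    (1e6 doses -> ~2517 kg, ~469 L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError, DomainError

__all__ = ["ShipmentSpec", "BUILTIN_SPECS", "get_spec", "mass_for_doses", "liquid_volume_for_doses"]


@dataclass(frozen=True)
class ShipmentSpec:
    """Per-unit packaging specification of a vaccine presentation.

    ``unit_mass_kg`` is the shipped payload mass of one unit including its
    immediate packaging; ``unit_volume_liquid_l`` is the vaccine liquid only.
    Dry-ice fields describe the refrigerant charge accompanying one unit and
    how often it is renewed per shipment; they feed the ledger's dry-ice
    line.  ``packaging_mass_extra_kg`` is additional shipped packaging mass
    per unit beyond ``unit_mass_kg`` (zero for both built-ins).
    """

    name: str
    doses_per_vial: int
    vials_per_unit: int
    unit_mass_kg: float
    unit_volume_liquid_l: float
    dry_ice_per_unit_kg: float = 0.0
    dry_ice_refresh_count: int = 0
    packaging_mass_extra_kg: float = 0.0
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.doses_per_vial < 1 or self.vials_per_unit < 1:
            raise DomainError("doses_per_vial and vials_per_unit must be >= 1")
        if min(self.unit_mass_kg, self.unit_volume_liquid_l, self.dry_ice_per_unit_kg,
               self.dry_ice_refresh_count, self.packaging_mass_extra_kg) < 0:
            raise DomainError("masses, volumes and counts must be >= 0")

    @property
    def doses_per_unit(self) -> int:
        return self.doses_per_vial * self.vials_per_unit

    @property
    def shipped_mass_per_unit_kg(self) -> float:
        return self.unit_mass_kg + self.packaging_mass_extra_kg


BUILTIN_SPECS: dict[str, ShipmentSpec] = {
    "BNT162b2": ShipmentSpec(
        name="BNT162b2",
        doses_per_vial=6,
        vials_per_unit=975,
        unit_mass_kg=36.0,
        # 5850 doses of 0.375 mL each after dilution
        unit_volume_liquid_l=5850 * 0.375e-3,
        dry_ice_per_unit_kg=23.0,
        dry_ice_refresh_count=2,
        packaging_mass_extra_kg=0.0,
        metadata={
            "unit": "carton of 5 trays in thermal container",
            "thermal_container_packaging_kg": 3.0,
            "dry_ice_volume_l": 15.0,
            "undiluted_ml_per_vial": 0.45,
        },
    ),
    "mRNA-1273": ShipmentSpec(
        name="mRNA-1273",
        doses_per_vial=10,
        vials_per_unit=11_520,
        unit_mass_kg=290.0,
        unit_volume_liquid_l=54.0,
        metadata={
            "unit": "pallet of 8 containers (12 cartons each)",
            "ml_per_vial_nominal": 5.0,
            "volume_note": "54 L pallet volume / 115,200 doses = 0.469 mL per dose; "
                           "the nominal 5 mL per 10-dose vial would give 0.5 mL per dose",
        },
    ),
}


def get_spec(name: str) -> ShipmentSpec:
    try:
        return BUILTIN_SPECS[name]
    except KeyError:
        raise ConfigError(
            f"unknown shipment spec {name!r}; built-ins: {', '.join(BUILTIN_SPECS)}"
        ) from None


def mass_for_doses(spec: ShipmentSpec, n_doses: float, discrete: bool = False) -> float:
    """Shipped payload mass (kg) to deliver ``n_doses``.

    Proportional mode (default) scales linearly with the dose count; the
    discrete mode rounds the number of shipping units up, so its result is
    never smaller than the proportional one and exceeds it by less than one
    unit's mass.
    """
    if n_doses < 0:
        raise DomainError(f"n_doses must be >= 0, got {n_doses}")
    units = n_doses / spec.doses_per_unit
    if discrete:
        units = math.ceil(units)
    return units * spec.shipped_mass_per_unit_kg


def liquid_volume_for_doses(spec: ShipmentSpec, n_doses: float) -> float:
    """Vaccine liquid volume (L, packaging excluded) for ``n_doses``."""
    if n_doses < 0:
        raise DomainError(f"n_doses must be >= 0, got {n_doses}")
    return n_doses / spec.doses_per_unit * spec.unit_volume_liquid_l
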