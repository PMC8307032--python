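"""Categorized CO2e ledger for vaccine logistics scenarios.

The ledger collects line items (transport, manufacture, storage, waste) for
shipping ``N`` doses, totals them with and without transport, and propagates
per-line uncertainties in quadrature: absolute errors are combined as
``sqrt(sum_i (value_i * rel_error_i)^2)``, grouped into transport versus
everything else, and the two group errors combine in quadrature again, which
is algebraically identical to a single global quadrature.

Two built-in scenarios describe one million doses distributed in Germany:

* Scenario ``A`` — ultra-cold shipping on dry ice (payload ~6154 kg per
  million doses): intercontinental air freight, European trucking, last-mile
  delivery, patient traffic, materials, a six-month freezer farm, dry ice,
  regional refrigeration and plastics incineration.
* Scenario ``B`` — frozen shipping without dry ice (payload ~2517 kg), with
  a ten-day freezing-during-transport line instead of the dry-ice charge.

Both evaluate to per-dose footprints of ~0.2 and ~0.15 kg CO2e; roughly 94%
of the total is transport, which therefore dominates the error budget.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DomainError
from .factors import FactorRegistry, default_registry
from .packaging import ShipmentSpec, get_spec, mass_for_doses

__all__ = [
    "CATEGORIES",
    "LedgerItem",
    "Ledger",
    "ErrorBudget",
    "transport_item",
    "per_dose_material_item",
    "storage_item",
    "dry_ice_item",
    "waste_item",
    "fixed_item",
    "travel_item",
    "build_scenario_ledger",
    "builtin_scenario",
    "BUILTIN_SCENARIO_NAMES",
    "propagate_errors",
    "ledger_summary",
    "sheldon_e_factor",
    "car_km_equivalent",
    "ceil_to",
]

CATEGORIES = frozenset({"transport", "manufacture", "storage", "waste"})


@dataclass
class LedgerItem:
    """One line of the ledger: a labelled emission value with its uncertainty."""

    label: str
    category: str
    value: float  # kg CO2e; credits may be negative
    rel_error: float = 0.0
    formula_trace: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DomainError(f"unknown category {self.category!r}; expected {sorted(CATEGORIES)}")
        if self.rel_error < 0:
            raise DomainError(f"rel_error must be >= 0, got {self.rel_error}")
        if not math.isfinite(self.value):
            raise DomainError(f"item {self.label!r}: value must be finite")

    @property
    def abs_error(self) -> float:
        return abs(self.value) * self.rel_error


@dataclass
class Ledger:
    """Ordered collection of ledger items for ``n_doses`` of one scenario."""

    scenario_name: str
    n_doses: int
    items: list[LedgerItem] = field(default_factory=list)

    @property
    def total(self) -> float:
        return sum(i.value for i in self.items)

    @property
    def total_transport(self) -> float:
        return sum(i.value for i in self.items if i.category == "transport")

    @property
    def total_excl_transport(self) -> float:
        return sum(i.value for i in self.items if i.category != "transport")

    @property
    def per_dose(self) -> float:
        return self.total / self.n_doses

    @property
    def per_dose_excl_transport(self) -> float:
        return self.total_excl_transport / self.n_doses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [i.label for i in self.items],
                "category": [i.category for i in self.items],
                "value_kg": [i.value for i in self.items],
                "rel_error": [i.rel_error for i in self.items],
                "abs_error_kg": [i.abs_error for i in self.items],
                "formula": [i.formula_trace for i in self.items],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ErrorBudget:
    """Quadrature error budget split into transport and non-transport groups."""

    transport_abs: float
    other_abs: float

    @property
    def combined_abs(self) -> float:
        return math.hypot(self.transport_abs, self.other_abs)


# ---------------------------------------------------------------------------
# Item constructors
# ---------------------------------------------------------------------------

def _require_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")


def transport_item(
    label: str, distance_km: float, factor: float, mass_kg: float, rel_error: float = 0.0
) -> LedgerItem:
    """Freight leg: ``distance * factor * mass / 1000`` with a per-1000km-kg factor."""
    _require_nonneg(distance_km=distance_km, factor=factor, mass_kg=mass_kg, rel_error=rel_error)
    value = distance_km * factor * mass_kg / 1000.0
    trace = f"{distance_km:g} km x {factor:g} kg/(1000 km kg) x {mass_kg:g} kg"
    return LedgerItem(label, "transport", value, rel_error, trace)


def per_dose_material_item(
    label: str,
    mass_per_dose_kg: float,
    factor: float,
    n_doses: float,
    rel_error: float = 0.0,
    category: str = "manufacture",
) -> LedgerItem:
    """Material line: per-dose mass times a per-kg production factor times N."""
    _require_nonneg(mass_per_dose_kg=mass_per_dose_kg, factor=factor,
                    n_doses=n_doses, rel_error=rel_error)
    value = mass_per_dose_kg * factor * n_doses
    trace = f"{mass_per_dose_kg:g} kg/dose x {factor:g} kg CO2e/kg x N={n_doses:g}"
    return LedgerItem(label, category, value, rel_error, trace)


def storage_item(
    label: str, days: float, per_day_factor: float, rel_error: float = 0.0
) -> LedgerItem:
    """Cold-storage line: days of operation times a per-day appliance footprint."""
    _require_nonneg(days=days, per_day_factor=per_day_factor, rel_error=rel_error)
    value = days * per_day_factor
    return LedgerItem(label, "storage", value, rel_error, f"{days:g} d x {per_day_factor:g} kg/d")


def dry_ice_item(
    label: str,
    charge_kg: float,
    refreshes: int,
    n_doses: float,
    doses_per_unit: int,
    factor: float,
    rel_error: float = 0.0,
) -> LedgerItem:
    """Dry-ice refrigerant: charge per unit, renewed ``refreshes`` times per shipment."""
    _require_nonneg(charge_kg=charge_kg, refreshes=refreshes, n_doses=n_doses,
                    factor=factor, rel_error=rel_error)
    if doses_per_unit < 1:
        raise DomainError(f"doses_per_unit must be >= 1, got {doses_per_unit}")
    value = refreshes * charge_kg * (n_doses / doses_per_unit) * factor
    trace = (f"{refreshes:g} x {charge_kg:g} kg x N/{doses_per_unit:g} "
             f"x {factor:g} kg CO2e/kg")
    return LedgerItem(label, "storage", value, rel_error, trace)


def waste_item(
    label: str,
    mass_per_dose_kg: float,
    gross_factor: float,
    credit_factor: float,
    n_doses: float,
    rel_error: float = 0.0,
) -> LedgerItem:
    """Disposal line: per-dose waste mass times net (gross minus credit) factor.

    A credit factor larger than the gross factor yields a net negative value
    (an emission credit), which is permitted.
    """
    _require_nonneg(mass_per_dose_kg=mass_per_dose_kg, gross_factor=gross_factor,
                    credit_factor=credit_factor, n_doses=n_doses, rel_error=rel_error)
    value = n_doses * mass_per_dose_kg * (gross_factor - credit_factor)
    trace = (f"N x {mass_per_dose_kg:g} kg x ({gross_factor:g} - {credit_factor:g}) kg CO2e/kg")
    return LedgerItem(label, "waste", value, rel_error, trace)


def fixed_item(label: str, category: str, value: float, rel_error: float = 0.0,
               trace: str = "fixed input") -> LedgerItem:
    return LedgerItem(label, category, value, rel_error, trace)


def travel_item(
    label: str, km_per_person: float, factor_per_km: float, n_persons: float,
    rel_error: float = 0.0,
) -> LedgerItem:
    """Person travel: per-person distance times a per-km factor times head count."""
    _require_nonneg(km_per_person=km_per_person, factor_per_km=factor_per_km,
                    n_persons=n_persons, rel_error=rel_error)
    value = n_persons * km_per_person * factor_per_km
    trace = f"N={n_persons:g} x {km_per_person:g} km x {factor_per_km:g} kg CO2e/km"
    return LedgerItem(label, "transport", value, rel_error, trace)


# ---------------------------------------------------------------------------
# Scenario builder
# ---------------------------------------------------------------------------

N_DOSES_REFERENCE = 1_000_000

#: Declarative configs for the two reference scenarios.  ``factor`` entries
#: name registry factors (a list means the factor values are summed); numbers
#: are taken literally.  Disabled entries keep a formula available without
#: contributing to the total.
_COMMON_ITEMS_HEAD = [
    dict(kind="fixed", label="Last-mile delivery (wholesaler to GP)", category="transport",
         value=566.0, rel_error=0.10),
    dict(kind="travel", label="Patient traffic to vaccination site",
         km_per_person=1.0, factor="patient_travel", rel_error=1.00),
    dict(kind="material", label="mRNA biochemical synthesis (30 ug/dose)",
         mass_per_dose_kg=30e-9, factor="mrna_process", rel_error=5.00),
    dict(kind="material", label="Glass vials (1 g/dose)",
         mass_per_dose_kg=0.001, factor="glass", rel_error=0.05),
    dict(kind="material", label="Paper, cardboard, ancillary kit (1 g/dose)",
         mass_per_dose_kg=0.001, factor="paper", rel_error=0.05),
    dict(kind="material", label="Syringes and sterilization (2 g/dose)",
         mass_per_dose_kg=0.002, factor=["polypropylene", "sterilization"], rel_error=0.05),
    dict(kind="storage", label="Freezer farm, 6 months at -20..-80 degC",
         days=180, factor="freezer_600l", rel_error=0.10),
]

_COMMON_ITEMS_TAIL = [
    dict(kind="fixed", label="Refrigerator in regional centers (2..8 degC)",
         category="storage", value=10.0, rel_error=0.20,
         trace="pinned reference value; 10 d x 0.1 kg/d formula available in config"),
    dict(kind="waste", label="Combustion of plastics (2 g/dose)",
         mass_per_dose_kg=0.002, gross_factor="plastics_combustion_gross",
         credit_factor="plastics_combustion_credit", rel_error=0.20),
    dict(kind="waste", label="Glass recycling credit (1 g/dose)", enabled=False,
         mass_per_dose_kg=0.001, gross_factor=0.0,
         credit_factor="glass_recycling_credit", rel_error=0.20),
    dict(kind="waste", label="Paper recycling credit (20 g/dose)", enabled=False,
         mass_per_dose_kg=0.02, gross_factor=0.0,
         credit_factor="paper_recycling_credit", rel_error=0.20),
]

BUILTIN_SCENARIOS: dict[str, dict] = {
    "A": dict(
        name="A",
        description="BNT162b2-style ultra-cold chain with dry ice",
        presentation="BNT162b2",
        n_doses=N_DOSES_REFERENCE,
        round_mass_to_kg=True,
        items=[
            dict(kind="transport", label="Air freight (USA-Europe)",
                 distance_km=6200, factor="air_freight_rfi", rel_error=0.50),
            dict(kind="transport", label="Truck (European distribution)",
                 distance_km=1000, factor="truck_payload", rel_error=0.20),
            *_COMMON_ITEMS_HEAD,
            dict(kind="dry_ice", label="Dry ice for shipping (2 x 5 days per carton)",
                 factor="dry_ice", rel_error=0.03),
            *_COMMON_ITEMS_TAIL,
        ],
    ),
    "B": dict(
        name="B",
        description="mRNA-1273-style frozen chain without dry ice",
        presentation="mRNA-1273",
        n_doses=N_DOSES_REFERENCE,
        round_mass_to_kg=True,
        items=[
            dict(kind="transport", label="Air freight (USA-Europe)",
                 distance_km=6200, factor="air_freight_rfi", rel_error=0.50),
            dict(kind="transport", label="Truck (European distribution)",
                 distance_km=1000, factor="truck_payload", rel_error=0.20),
            *_COMMON_ITEMS_HEAD,
            dict(kind="storage", label="Freezing during transport, 10 days at -40 degC",
                 days=10, factor="freezer_600l", rel_error=0.10),
            *_COMMON_ITEMS_TAIL,
        ],
    ),
}

BUILTIN_SCENARIO_NAMES = tuple(BUILTIN_SCENARIOS)


def builtin_scenario(name: str) -> dict:
    """Deep copy of a built-in scenario config (safe to modify)."""
    try:
        return copy.deepcopy(BUILTIN_SCENARIOS[name])
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; built-ins: {', '.join(BUILTIN_SCENARIOS)}"
        ) from None


def _resolve_factor(spec, registry: FactorRegistry) -> float:
    """Resolve a factor entry: registry name, list of names (summed) or number."""
    if isinstance(spec, str):
        return registry.value(spec)
    if isinstance(spec, (list, tuple)):
        return sum(registry.value(s) if isinstance(s, str) else float(s) for s in spec)
    return float(spec)


def build_scenario_ledger(
    scenario: Mapping | str,
    registry: FactorRegistry | None = None,
) -> Ledger:
    """Evaluate a scenario config into a :class:`Ledger`.

    ``scenario`` is a built-in name or a config mapping with keys ``name``,
    ``presentation`` (a built-in :class:`~vaxfootprint.packaging.ShipmentSpec`
    name), ``n_doses`` and ``items``.  Transport legs resolve their payload
    mass from the presentation; by default the mass is rounded to whole kg so
    that reported lines match the precision of the reference figures.
    """
    if isinstance(scenario, str):
        scenario = builtin_scenario(scenario)
    registry = registry if registry is not None else default_registry()

    try:
        n_doses = int(scenario["n_doses"])
        item_specs: Sequence[Mapping] = scenario["items"]
        name = scenario.get("name", "unnamed")
    except KeyError as e:
        raise ConfigError(f"scenario config missing key {e.args[0]!r}") from None
    if n_doses < 0:
        raise ConfigError(f"n_doses must be >= 0, got {n_doses}")

    spec: ShipmentSpec | None = None
    mass_kg = scenario.get("mass_kg")
    if "presentation" in scenario:
        spec = get_spec(scenario["presentation"])
        if mass_kg is None:
            mass_kg = mass_for_doses(spec, n_doses)
            if scenario.get("round_mass_to_kg", True):
                mass_kg = round(mass_kg)

    items: list[LedgerItem] = []
    for raw in item_specs:
        if not raw.get("enabled", True):
            continue
        kind = raw.get("kind")
        label = raw.get("label", kind or "item")
        rel = float(raw.get("rel_error", 0.0))
        try:
            if kind == "transport":
                if mass_kg is None:
                    raise ConfigError(
                        f"item {label!r}: transport leg needs a presentation or mass_kg"
                    )
                items.append(transport_item(
                    label, float(raw["distance_km"]),
                    _resolve_factor(raw["factor"], registry),
                    float(raw.get("mass_kg", mass_kg)), rel))
            elif kind == "material":
                items.append(per_dose_material_item(
                    label, float(raw["mass_per_dose_kg"]),
                    _resolve_factor(raw["factor"], registry), n_doses, rel))
            elif kind == "storage":
                items.append(storage_item(
                    label, float(raw["days"]), _resolve_factor(raw["factor"], registry), rel))
            elif kind == "dry_ice":
                if spec is None:
                    raise ConfigError(f"item {label!r}: dry_ice line needs a presentation")
                items.append(dry_ice_item(
                    label,
                    float(raw.get("charge_kg", spec.dry_ice_per_unit_kg)),
                    int(raw.get("refreshes", spec.dry_ice_refresh_count)),
                    n_doses,
                    int(raw.get("doses_per_unit", spec.doses_per_unit)),
                    _resolve_factor(raw["factor"], registry), rel))
            elif kind == "waste":
                items.append(waste_item(
                    label, float(raw["mass_per_dose_kg"]),
                    _resolve_factor(raw["gross_factor"], registry),
                    _resolve_factor(raw["credit_factor"], registry), n_doses, rel))
            elif kind == "travel":
                items.append(travel_item(
                    label, float(raw["km_per_person"]),
                    _resolve_factor(raw["factor"], registry), n_doses, rel))
            elif kind == "fixed":
                items.append(fixed_item(label, raw["category"], float(raw["value"]), rel,
                                        raw.get("trace", "fixed input")))
            else:
                raise ConfigError(f"item {label!r}: unknown kind {kind!r}")
        except KeyError as e:
            raise ConfigError(f"item {label!r}: missing key {e.args[0]!r}") from None

    return Ledger(scenario_name=name, n_doses=n_doses, items=items)


# ---------------------------------------------------------------------------
# Error propagation and summaries
# ---------------------------------------------------------------------------

def propagate_errors(ledger: Ledger) -> ErrorBudget:
    """First-order quadrature propagation of per-line absolute errors.

    Lines are assumed independent; the transport group and the remainder are
    each combined as root-sum-of-squares, and the two group errors combine
    the same way (identical to one global quadrature over all lines).
    """
    t2 = sum(i.abs_error ** 2 for i in ledger.items if i.category == "transport")
    o2 = sum(i.abs_error ** 2 for i in ledger.items if i.category != "transport")
    return ErrorBudget(transport_abs=math.sqrt(t2), other_abs=math.sqrt(o2))


def ceil_to(x: float, decimals: int) -> float:
    """Round a non-negative error bound up at the given decimal place."""
    scale = 10 ** decimals
    return math.ceil(x * scale - 1e-9) / scale


def ledger_summary(ledger: Ledger, precision: int = 3) -> dict:
    """Headline numbers of a ledger: totals, per-dose values and error budget.

    Per-dose values are rounded half-even at ``precision`` decimals; absolute
    errors are rounded *up* at the same precision, the conservative convention
    for reported uncertainty bounds.
    """
    budget = propagate_errors(ledger)
    n = ledger.n_doses
    return {
        "scenario": ledger.scenario_name,
        "n_doses": n,
        "total_kg": ledger.total,
        "total_transport_kg": ledger.total_transport,
        "total_excl_transport_kg": ledger.total_excl_transport,
        "transport_share": ledger.total_transport / ledger.total if ledger.total else 0.0,
        "per_dose_kg": round(ledger.per_dose, precision) if n else 0.0,
        "per_dose_error_kg": ceil_to(budget.combined_abs / n, precision) if n else 0.0,
        "per_dose_excl_transport_kg": round(ledger.per_dose_excl_transport, precision) if n else 0.0,
        "per_dose_excl_transport_error_kg": ceil_to(budget.other_abs / n, precision) if n else 0.0,
        "error_budget_kg": {
            "transport_abs": budget.transport_abs,
            "other_abs": budget.other_abs,
            "combined_abs": budget.combined_abs,
        },
    }


def sheldon_e_factor(waste_mass_kg: float, product_mass_kg: float) -> float:
    """Green-chemistry E-factor: kg of waste per kg of product.

    Oil refining sits below 0.1; pharmaceutical fine synthesis can exceed 100.
    """
    if product_mass_kg <= 0:
        raise DomainError(f"product mass must be > 0, got {product_mass_kg}")
    if waste_mass_kg < 0:
        raise DomainError(f"waste mass must be >= 0, got {waste_mass_kg}")
    return waste_mass_kg / product_mass_kg


def car_km_equivalent(emissions_kg: float, car_factor_kg_per_km: float = 0.2) -> float:
    """Distance a combustion-engine car would drive to emit ``emissions_kg``."""
    if car_factor_kg_per_km <= 0:
        raise DomainError(f"car factor must be > 0, got {car_factor_kg_per_km}")
    return emissions_kg / car_factor_kg_per_km
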