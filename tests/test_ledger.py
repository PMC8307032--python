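import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxfootprint import (Ledger, LedgerItem, build_scenario_ledger, builtin_scenario,
                          car_km_equivalent, ledger_summary, propagate_errors,
                          sheldon_e_factor)
from vaxfootprint.errors import ConfigError, DomainError
from vaxfootprint.ledger import (dry_ice_item, per_dose_material_item, storage_item,
                                 transport_item, waste_item)

N = 1_000_000


class TestItemConstructors:
    def test_air_freight_leg(self):
        item = transport_item("air", 6200, 2.3, 6154, 0.5)
        assert item.value == pytest.approx(87_756, abs=0.1)
        assert item.category == "transport"
        assert item.abs_error == pytest.approx(0.5 * item.value)

    def test_truck_leg(self):
        assert transport_item("truck", 1000, 0.2, 6154, 0.2).value == pytest.approx(1231, abs=0.5)

    def test_empty_load(self):
        assert transport_item("air", 6200, 2.3, 0.0).value == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            transport_item("air", -1, 2.3, 6154)

    @pytest.mark.parametrize(
        "mass, factor, expected",
        [(0.001, 0.72, 720.0), (0.001, 0.61, 610.0), (0.0, 5.0, 0.0)],
    )
    def test_material_lines(self, mass, factor, expected):
        assert per_dose_material_item("m", mass, factor, N).value == pytest.approx(expected)

    @pytest.mark.parametrize("days, per_day, expected", [(180, 8, 1440), (10, 8, 80), (0, 8, 0)])
    def test_storage_lines(self, days, per_day, expected):
        assert storage_item("s", days, per_day).value == expected

    def test_dry_ice_reference_line(self):
        item = dry_ice_item("d", 23, 2, N, 5850, 0.15)
        assert item.value == pytest.approx(1180, abs=1)

    def test_dry_ice_no_refresh_is_zero(self):
        assert dry_ice_item("d", 23, 0, N, 5850, 0.15).value == 0.0

    def test_dry_ice_unit_case(self):
        assert dry_ice_item("d", 1, 1, 5850, 5850, 1.0).value == pytest.approx(1.0)

    def test_dry_ice_zero_doses_per_unit_rejected(self):
        with pytest.raises(DomainError):
            dry_ice_item("d", 23, 2, N, 0, 0.15)

    @pytest.mark.parametrize(
        "mass, gross, credit, expected",
        [(0.002, 2.41, 0.65, 3520.0), (0.001, 0.4, 0.4, 0.0), (0.0, 9.9, 0.1, 0.0)],
    )
    def test_waste_lines(self, mass, gross, credit, expected):
        assert waste_item("w", mass, gross, credit, N).value == pytest.approx(expected)


# Expected line values of the built-in ultra-cold scenario per 1e6 doses.
SCENARIO_A_ROWS = [
    ("Air freight", 87_756.0, 1.0),
    ("Truck", 1_230.8, 0.1),
    ("Last-mile", 566.0, 0.01),
    ("Patient traffic", 100_000.0, 0.01),
    ("mRNA", 15.0, 0.01),
    ("Glass", 720.0, 0.01),
    ("Paper", 610.0, 0.01),
    ("Syringes", 4_540.0, 0.01),
    ("Freezer farm", 1_440.0, 0.01),
    ("Dry ice", 1_179.5, 0.1),
    ("Refrigerator", 10.0, 0.01),
    ("Combustion", 3_520.0, 0.01),
]


def test_scenario_a_row_by_row(ledger_a):
    assert len(ledger_a.items) == len(SCENARIO_A_ROWS)
    for item, (label, value, tol) in zip(ledger_a.items, SCENARIO_A_ROWS):
        assert label.split()[0].lower() in item.label.lower()
        assert item.value == pytest.approx(value, abs=tol), item.label


def test_scenario_totals_per_dose(ledger_a, ledger_b):
    assert round(ledger_a.per_dose, 3) == 0.202
    assert round(ledger_b.per_dose, 3) == 0.148
    assert round(ledger_a.per_dose_excl_transport, 3) == 0.012
    assert round(ledger_b.per_dose_excl_transport, 3) == 0.011


def test_scenario_difference(ledger_a, ledger_b):
    incl = ledger_a.total - ledger_b.total
    excl = ledger_a.total_excl_transport - ledger_b.total_excl_transport
    assert incl == pytest.approx(54_000, abs=1_000)
    assert excl == pytest.approx(1_100, abs=5)


def test_total_is_sum_of_items(ledger_a):
    assert ledger_a.total == pytest.approx(sum(i.value for i in ledger_a.items))
    assert ledger_a.total == pytest.approx(
        ledger_a.total_transport + ledger_a.total_excl_transport
    )


def test_error_propagation_reference(ledger_a):
    budget = propagate_errors(ledger_a)
    assert budget.transport_abs == pytest.approx(109_203, abs=5)
    assert budget.other_abs == pytest.approx(760, abs=2)
    assert budget.combined_abs == pytest.approx(109_206, abs=5)


def test_single_item_budget_is_its_own_error():
    ledger = Ledger("one", N, [LedgerItem("x", "storage", 100.0, 0.25)])
    budget = propagate_errors(ledger)
    assert budget.combined_abs == pytest.approx(25.0)
    assert budget.transport_abs == 0.0


def test_summary_rounding_conventions(ledger_a):
    s = ledger_summary(ledger_a)
    assert s["per_dose_kg"] == 0.202
    assert s["per_dose_error_kg"] == 0.110  # 0.10920... rounded *up*
    assert s["per_dose_excl_transport_error_kg"] == 0.001
    assert 0.9 < s["transport_share"] < 0.99


@given(
    st.lists(
        st.tuples(st.floats(0, 1e5), st.floats(0, 2)),
        min_size=1, max_size=12,
    )
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_quadrature_bounds(pairs):
    items = [LedgerItem(f"i{k}", "storage", v, r) for k, (v, r) in enumerate(pairs)]
    ledger = Ledger("h", N, items)
    combined = propagate_errors(ledger).combined_abs
    errs = [i.abs_error for i in items]
    assert combined <= sum(errs) + 1e-6
    assert combined >= max(errs) - 1e-6


@given(c=st.floats(0.1, 100))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_scaling_homogeneity(c):
    base = build_scenario_ledger("A")
    scaled = Ledger("scaled", base.n_doses,
                    [LedgerItem(i.label, i.category, i.value * c, i.rel_error)
                     for i in base.items])
    assert scaled.total == pytest.approx(c * base.total)
    assert propagate_errors(scaled).combined_abs == pytest.approx(
        c * propagate_errors(base).combined_abs)


def test_empty_scenario_totals_zero():
    ledger = build_scenario_ledger({"name": "empty", "n_doses": N, "items": []})
    assert ledger.total == 0.0
    assert propagate_errors(ledger).combined_abs == 0.0


def test_unknown_factor_reported():
    scenario = builtin_scenario("A")
    scenario["items"][0]["factor"] = "warp_drive"
    with pytest.raises(ConfigError, match="warp_drive"):
        build_scenario_ledger(scenario)


def test_unknown_scenario_name():
    with pytest.raises(ConfigError, match="Z"):
        build_scenario_ledger("Z")


def test_ledger_csv_output(ledger_a, tmp_path):
    path = tmp_path / "ledger.csv"
    ledger_a.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert len(df) == len(ledger_a.items)
    assert df["value_kg"].sum() == pytest.approx(ledger_a.total)


class TestAuxiliaryMetrics:
    def test_sheldon_examples(self):
        assert sheldon_e_factor(0.0, 1.0) == 0.0
        assert sheldon_e_factor(100.0, 1.0) == 100.0  # pharmaceutical upper scale
        assert sheldon_e_factor(0.05, 1.0) < 0.1      # oil-refining regime

    def test_sheldon_zero_product_rejected(self):
        with pytest.raises(DomainError):
            sheldon_e_factor(1.0, 0.0)

    @pytest.mark.parametrize(
        "emissions, expected", [(54_000, 270_000), (1_100, 5_500), (0.0, 0.0)]
    )
    def test_car_km_equivalent(self, emissions, expected):
        assert car_km_equivalent(emissions, 0.2) == pytest.approx(expected)

    def test_car_km_zero_factor_rejected(self):
        with pytest.raises(DomainError):
            car_km_equivalent(100.0, 0.0)
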