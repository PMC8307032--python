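import numpy as np
import pytest

from vaxfootprint import (GeographyParams, Region, assign_pharmacies_to_wholesalers,
                          attach_gps_to_pharmacies, build_scenario_ledger,
                          default_registry, generate_geography, simulate_month)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def ledger_a():
    return build_scenario_ledger("A")


@pytest.fixture(scope="session")
def ledger_b():
    return build_scenario_ledger("B")


SMALL_PARAMS = GeographyParams(
    n_receipt_hubs=4,
    n_intermediary_hubs=7,
    n_pharmacies=600,
    n_gp_practices=1400,
    region=Region(200.0, 180.0),
    n_metro_clusters=4,
    metro_sigma_km=12.0,
)


def make_small_model(seed=42, labelled=True):
    model = generate_geography(SMALL_PARAMS, seed=seed)
    if labelled:
        assign_pharmacies_to_wholesalers(model, seed=seed)
        attach_gps_to_pharmacies(model)
    return model


@pytest.fixture()
def small_model():
    return make_small_model()


@pytest.fixture(scope="session")
def germany_model():
    """Full reference-scale network, labelled and GP-attached."""
    model = generate_geography(seed=1)
    assign_pharmacies_to_wholesalers(model, seed=1)
    attach_gps_to_pharmacies(model)
    return model


@pytest.fixture(scope="session")
def germany_result(germany_model):
    return simulate_month(germany_model, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
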