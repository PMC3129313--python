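import numpy as np
import pytest

from vaxchain.catalog import default_catalog, default_cost_inputs
from vaxchain.engine import LocationState
from vaxchain.fixtures import (
    FixtureParams,
    default_demand,
    generate_network,
    miniature_params,
)
from vaxchain.network import Location, StorageDevice


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cost_inputs():
    return default_cost_inputs()


@pytest.fixture(scope="session")
def mini_network():
    return generate_network(miniature_params(), seed=3)


@pytest.fixture(scope="session")
def mini_demand(mini_network):
    return default_demand(mini_network)


@pytest.fixture(scope="session")
def full_network():
    return generate_network(FixtureParams(), seed=1)


@pytest.fixture(scope="session")
def full_demand(full_network):
    return default_demand(full_network)


@pytest.fixture
def clinic_state():
    """A clinic with effectively unbounded cold storage, for session
    tests that control stock explicitly."""
    loc = Location(
        location_id="CLINIC",
        level="clinic",
        devices=[
            StorageDevice("fridge", "refrigerator", 1e12),
            StorageDevice("freezer", "freezer", 1e12),
        ],
    )
    return LocationState(loc)


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)
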