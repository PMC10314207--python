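import pytest
from hypothesis import settings

import gastrosim as gs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def itraconazole():
    return gs.load_drug("itraconazole")


@pytest.fixture(scope="session")
def indinavir():
    return gs.load_drug("indinavir")


@pytest.fixture(scope="session")
def sporanox_nowater():
    return gs.load_protocol("sporanox_fasted_nowater")


@pytest.fixture(scope="session")
def sporanox_water():
    return gs.load_protocol("sporanox_fasted_water")


@pytest.fixture(scope="session")
def indinavir_fasted():
    return gs.load_protocol("indinavir_fasted")


@pytest.fixture(scope="session")
def indinavir_fed_protein():
    return gs.load_protocol("indinavir_fed_protein")


@pytest.fixture(scope="session")
def all_fixture_pairs(itraconazole, indinavir):
    """(protocol, drug) for every packaged scenario."""
    pairs = []
    for name in gs.list_fixtures()["protocols"]:
        drug = itraconazole if name.startswith("sporanox") else indinavir
        pairs.append((gs.load_protocol(name), drug))
    return pairs


@pytest.fixture(scope="session")
def fasted_marker_run(indinavir_fasted):
    """One deterministic inert-marker simulation on the fasted design."""
    return gs.inert_marker_run(indinavir_fasted, dense_step=None)
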