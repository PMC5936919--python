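import pytest

from pertraction import carvone_heptane_scenario, wilke_chang_diffusivity


@pytest.fixture(scope="session")
def scenario():
    return carvone_heptane_scenario()


@pytest.fixture(scope="session")
def carvone(scenario):
    return scenario.solute


@pytest.fixture(scope="session")
def water(scenario):
    return scenario.aqueous


@pytest.fixture(scope="session")
def heptane(scenario):
    return scenario.organic


@pytest.fixture(scope="session")
def module(scenario):
    return scenario.module


@pytest.fixture(scope="session")
def d_water(carvone, water):
    return wilke_chang_diffusivity(carvone, water, 298.15)


@pytest.fixture(scope="session")
def d_heptane(carvone, heptane):
    return wilke_chang_diffusivity(carvone, heptane, 298.15)
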