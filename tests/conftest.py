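import pytest

import spinerel as sr


@pytest.fixture(scope="session")
def topology():
    return sr.default_topology()


@pytest.fixture(scope="session")
def resistance_entries():
    return sr.builtin_resistance_table()


@pytest.fixture(scope="session")
def resistances(resistance_entries):
    return sr.index_resistances(resistance_entries)


@pytest.fixture(scope="session")
def areas():
    return sr.builtin_area_table()


@pytest.fixture()
def normal_demands(topology, areas):
    return sr.generate_demand_table(
        topology, sr.LoadCase(70.0), sr.CurvatureProfile.normal(),
        seed=11, areas=areas,
    )


@pytest.fixture()
def scoliosis_demands(topology, areas):
    return sr.generate_demand_table(
        topology, sr.LoadCase(70.0), sr.CurvatureProfile.scoliosis(),
        seed=11, areas=areas,
    )
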