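import pytest

from patchfishery import preset, solve_interior_equilibrium


@pytest.fixture(scope="session")
def figset_params():
    return preset("figset").params


@pytest.fixture(scope="session")
def table1_params():
    return preset("table1").params


@pytest.fixture(scope="session")
def figset_eq(figset_params):
    return solve_interior_equilibrium(figset_params)


@pytest.fixture(scope="session")
def table1_eq(table1_params):
    return solve_interior_equilibrium(table1_params)
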