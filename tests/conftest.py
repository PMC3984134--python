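import pytest

from symdeep.simulate import ErrorModel, default_panel


@pytest.fixture(scope="session")
def panel_and_genomes():
    genomes, panel = default_panel(seed=11)
    return genomes, panel


@pytest.fixture(scope="session")
def genomes(panel_and_genomes):
    return panel_and_genomes[0]


@pytest.fixture(scope="session")
def panel(panel_and_genomes):
    return panel_and_genomes[1]


@pytest.fixture()
def zero_error():
    return ErrorModel.zero_error(seed=5)
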