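import numpy as np
import pytest

from dropcoop import scenario_preset


@pytest.fixture(scope="session")
def dependent():
    return scenario_preset("dependent")


@pytest.fixture(scope="session")
def costless():
    return scenario_preset("costless_background")


@pytest.fixture(scope="session")
def costly():
    return scenario_preset("costly_background")


@pytest.fixture
def rng():
    return np.random.default_rng(20210505)
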