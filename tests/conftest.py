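import numpy as np
import pytest

from synerfit import load_dose_grids, load_uniform_design, load_synergy_design


@pytest.fixture(scope="session")
def uniform_design():
    return load_uniform_design()


@pytest.fixture(scope="session")
def synergy_design():
    return load_synergy_design()


@pytest.fixture(scope="session")
def grids():
    return load_dose_grids()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
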