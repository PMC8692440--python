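import logging

import numpy as np
import pytest

from protrack import materials
from protrack.rudd_xs import get_table

logging.getLogger("protrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def water_mat():
    return materials.water()


@pytest.fixture(scope="session")
def teg_mat():
    return materials.teg()


@pytest.fixture(scope="session")
def helium_mat():
    return materials.helium()


@pytest.fixture(scope="session")
def water_table(water_mat):
    return get_table(water_mat)


@pytest.fixture(scope="session")
def teg_table(teg_mat):
    return get_table(teg_mat)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
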