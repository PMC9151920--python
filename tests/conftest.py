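import numpy as np
import pytest

from xlogistic import datasets


@pytest.fixture(scope="session")
def pre():
    return datasets.presets()


@pytest.fixture(scope="session")
def seeding1(pre):
    return pre.table2_hexads[1]


@pytest.fixture(scope="session")
def seeding2(pre):
    return pre.table2_hexads[2]


@pytest.fixture(scope="session")
def seeding3(pre):
    return pre.table2_hexads[3]


@pytest.fixture(scope="session")
def table3(pre):
    return pre.table3_reference


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
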