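import numpy as np
import pytest

import hkafsim as hk


@pytest.fixture(scope="session")
def specs():
    return hk.builtin_subpopulations()


@pytest.fixture(scope="session")
def benzene():
    return hk.get_chemical("benzene")


@pytest.fixture(scope="session")
def dioxane():
    return hk.get_chemical("dioxane")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
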