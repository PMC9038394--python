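import numpy as np
import pytest

from asmote import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def separable():
    return make_fixture("separable", seed=7)


@pytest.fixture(scope="session")
def overlapping():
    return make_fixture("overlapping", seed=7)


@pytest.fixture(scope="session")
def null_data():
    return make_fixture("null", seed=7)
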