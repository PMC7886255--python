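import numpy as np
import pytest

from boolobs import load_fixture


@pytest.fixture
def ex2_first():
    return load_fixture("example2_first")


@pytest.fixture
def ex2_second():
    return load_fixture("example2_second")


@pytest.fixture
def ex3():
    return load_fixture("example3_attractors")


@pytest.fixture
def seven_gene():
    return load_fixture("seven_gene")


@pytest.fixture
def drosophila():
    return load_fixture("drosophila")


@pytest.fixture
def example1_net():
    return load_fixture("example1_bn")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
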