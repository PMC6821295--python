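import numpy as np
import pytest

from fscodes.codes import builtin_code


@pytest.fixture(scope="session")
def standard():
    return builtin_code("standard")


@pytest.fixture(scope="session")
def red20():
    return builtin_code("red20")


@pytest.fixture(scope="session")
def red15():
    return builtin_code("red15")


@pytest.fixture(scope="session")
def fs20():
    return builtin_code("fs20")


@pytest.fixture(scope="session")
def fs16():
    return builtin_code("fs16")


@pytest.fixture(scope="session")
def colorado():
    return builtin_code("colorado")


@pytest.fixture(scope="session")
def fsquad():
    return builtin_code("fsquad")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
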