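import numpy as np
import pytest

from vdga import GapModel, generate_family, load_matrix


@pytest.fixture(scope="session")
def pam250():
    return load_matrix("pam250")


@pytest.fixture(scope="session")
def gaps():
    return GapModel()


@pytest.fixture(scope="session")
def small_family():
    """A small, quick family: 5 sequences of ancestor length 60."""
    return generate_family(seed=11, n=5, length=60)


@pytest.fixture(scope="session")
def default_family():
    """The generator's default regime: 8 sequences, ancestor length 150."""
    return generate_family(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
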