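import pytest

from substim import CANONICAL_GRID
from substim import synth


@pytest.fixture(scope="session")
def grid():
    return CANONICAL_GRID


@pytest.fixture(scope="session")
def observer():
    return synth.synthetic_observer()


@pytest.fixture(scope="session")
def template():
    return synth.synthetic_density_template()


@pytest.fixture(scope="session")
def device():
    return synth.default_device()


@pytest.fixture(scope="session")
def vlambda():
    return synth.synthetic_vlambda()


@pytest.fixture(scope="session")
def cmfs():
    return synth.synthetic_cmfs()
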