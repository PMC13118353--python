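import pytest

from ocusim import (
    default_drug_params,
    default_physiology,
    default_target_params,
)

#: loosened solver settings for tests that only need qualitative accuracy
FAST_SOLVER = dict(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def target():
    return default_target_params()


@pytest.fixture(scope="session")
def adalimumab():
    return default_drug_params("adalimumab")


@pytest.fixture(scope="session")
def golimumab():
    return default_drug_params("golimumab")


@pytest.fixture(scope="session")
def infliximab():
    return default_drug_params("infliximab")
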