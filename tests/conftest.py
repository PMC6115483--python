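import numpy as np
import pytest

from shiftsim import MotorUnitPool, RecruitmentPolicy, generate_pool


@pytest.fixture(scope="session")
def pool100():
    """Default 100-unit pool with power-distributed twitch forces."""
    return generate_pool()


@pytest.fixture(scope="session")
def equal4():
    """Four identical units: recruitment counts become deterministic."""
    return MotorUnitPool(np.ones(4))


@pytest.fixture(scope="session")
def uniform():
    return RecruitmentPolicy.uniform()


@pytest.fixture(scope="session")
def biased():
    return RecruitmentPolicy.small_biased(1.0)
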