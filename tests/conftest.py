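import numpy as np
import pytest

from coxsens import SurvivalDataset, make_hivlike, make_sim5, make_tiny


@pytest.fixture
def tiny() -> SurvivalDataset:
    return make_tiny()


@pytest.fixture(scope="session")
def sim5() -> SurvivalDataset:
    """One n=1000 draw from the simulation-study generator (no tied times)."""
    return make_sim5(seed=1)


@pytest.fixture(scope="session")
def hivlike() -> SurvivalDataset:
    return make_hivlike(seed=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
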