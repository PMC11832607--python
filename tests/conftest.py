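import numpy as np
import pytest

from crimpsim import (
    ScenarioConfig,
    default_coefficient_set,
    default_covariate_model,
)
from crimpsim.amputation import default_pattern_library
from crimpsim.evaluation import prepare_scenario


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """Desk-scale scenario shared by the engine tests."""
    return ScenarioConfig(n_super=20_000, n_sample=1000, n_reps=2,
                          m_imputations=3, p_missing=0.5, seed=20240626)


@pytest.fixture(scope="session")
def small_world(small_scenario):
    """(complete superpop, amputed superpop, truth) at n=20,000."""
    return prepare_scenario(small_scenario)


@pytest.fixture(scope="session")
def sample_amputed(small_world, small_scenario):
    """One n=1000 amputed sample plus its complete counterpart."""
    superpop, amputed, _ = small_world
    rng = np.random.default_rng(99)
    idx = rng.choice(len(superpop), size=small_scenario.n_sample, replace=False)
    return (amputed.iloc[idx].reset_index(drop=True),
            superpop.iloc[idx].reset_index(drop=True))


@pytest.fixture(scope="session")
def cov_model():
    return default_covariate_model()


@pytest.fixture(scope="session")
def coefficients():
    return default_coefficient_set()


@pytest.fixture(scope="session")
def pattern_library():
    return default_pattern_library()
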