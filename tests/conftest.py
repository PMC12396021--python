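import numpy as np
import pytest

from beclin_duality import ParameterSet, sample_lhs, scenario_fractions


@pytest.fixture(scope="session")
def r_params() -> ParameterSet:
    """The representative (Table-1) parameter set."""
    return ParameterSet.representative()


@pytest.fixture(scope="session")
def small_ensemble():
    """A small LHS ensemble shared by property tests."""
    return sample_lhs(200, seed=99)


@pytest.fixture(scope="session")
def eight_scenario_run():
    """A reduced paired run of all eight canonical scenarios."""
    return scenario_fractions(sample_lhs(500, seed=1234))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
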