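import numpy as np
import pytest

from earlylate import (
    PopulationParams,
    TrialDesign,
    simulate_conditional_pair,
)


@pytest.fixture(scope="session")
def design() -> TrialDesign:
    return TrialDesign()


@pytest.fixture(scope="session")
def null_params() -> PopulationParams:
    """Strict null: no effects, no between-trial heterogeneity."""
    return PopulationParams(bx=0.0, by=0.0, tau_x=0.0, tau_y=0.0)


@pytest.fixture(scope="session")
def alt_params() -> PopulationParams:
    return PopulationParams(bx=0.6, by=0.6, tau_x=0.0, tau_y=0.0)


@pytest.fixture(scope="session")
def small_dataset(null_params, design):
    """One seeded conditional trial pair (selection at alpha2 = 0.05)."""
    return simulate_conditional_pair(null_params, design, np.random.default_rng(421))
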