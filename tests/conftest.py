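import numpy as np
import pytest

from gaitcausal.bart import BARTConfig
from gaitcausal.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by read-only tests."""
    cohort, exams, truth = generate_cohort(SyntheticConfig(n=600, seed=101))
    return cohort, exams, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def fast_bart():
    """A short-chain sampler config for unit tests."""
    return BARTConfig(num_trees=20, k=2.0, n_burn=300, n_draws=300, seed=9)
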