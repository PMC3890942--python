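import numpy as np
import pytest

from percross import EnvConfig, generate_dataset
from percross.pipeline import analyze_recordings

#: Seed used for every stochastic fixture in the suite.
SUITE_SEED = 20260922


@pytest.fixture(scope="session")
def cfg():
    return EnvConfig()


@pytest.fixture(scope="session")
def short_cfg():
    """A 20-second trial config, identical geometry, for fast simulations."""
    return EnvConfig(trial_duration=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def mixed_dataset():
    """Full-size tournament: 17 teams x 15 trials, turn-takers and scanners."""
    return generate_dataset(17, 15, controller_mix="mixed", seed=SUITE_SEED)


@pytest.fixture(scope="session")
def mixed_analysis(mixed_dataset):
    return analyze_recordings(
        mixed_dataset.recordings, mixed_dataset.questionnaires, seed=SUITE_SEED
    )
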