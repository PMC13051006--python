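import numpy as np
import pandas as pd
import pytest

from afrmatch import GeneratorParams, simulate_experiment, simulate_study


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(n_participants=20, seed=7)


@pytest.fixture(scope="session")
def small_study(small_params):
    """Shared face set, three regimes, 20 participants each."""
    trials, participants, truth = simulate_study(small_params, seed=7)
    return trials, participants, truth


@pytest.fixture(scope="session")
def graded_cohort(small_params):
    trials, participants, truth = simulate_experiment(small_params, "graded", seed=21)
    return trials, participants, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
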