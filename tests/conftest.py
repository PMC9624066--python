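import numpy as np
import pandas as pd
import pytest

from neurofuse.design import make_design
from neurofuse.generator import GeneratorParams, simulate_eeg


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """Small but non-trivial generator settings shared across tests."""
    return GeneratorParams(
        n_participants=2,
        n_channels=10,
        sfreq=200.0,
        epoch_window=(-50.0, 250.0),
        n_repetitions=6,
        noise_sd=1.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    return make_design(5, 2, 5, 6)


@pytest.fixture(scope="session")
def small_eeg(small_params, small_design):
    return simulate_eeg(small_params, small_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
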