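import numpy as np
import pytest
from hypothesis import settings

import gaitnorm as gn

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def published_table():
    return gn.load_published_table()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """10 subjects x 5 conditions, single trial, exact model values."""
    return gn.generate_dataset(
        gn.SynthConfig(seed=3, n_subjects=10, trials_per_condition=1, noise_scale=0.0)
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """30 subjects x 5 conditions x 2 trials with RMSE-scaled key-point noise."""
    return gn.generate_dataset(
        gn.SynthConfig(seed=7, n_subjects=30, trials_per_condition=2, noise_scale=1.0)
    )


@pytest.fixture(scope="session")
def wavy_cycles():
    """50 gait-like cycles with smooth band-limited waveform noise (1 deg SD)."""
    ds = gn.generate_dataset(
        gn.SynthConfig(
            seed=5,
            n_subjects=10,
            trials_per_condition=1,
            noise_scale=0.0,
            waveform_noise_sd=1.0,
        )
    )
    return ds.trials


@pytest.fixture
def median_predictors():
    return gn.PredictorVector(v_star=0.45, age=38.0, sex=1, bmi=24.0)
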