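import numpy as np
import pandas as pd
import pytest

from impulsewm import Design, EpochSet, generate_epochs
from impulsewm.pipeline import prepare_participant


def make_epochs(n_trials=24, n_channels=6, n_times=11, seed=0, t0=-200.0):
    """Small hand-rolled EpochSet with uniform orientations."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_channels, n_times))
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "orientation_deg": rng.uniform(0, 180, n_trials),
            "trial_type": ["long"] * n_trials,
            "impulse_onset_ms": np.full(n_trials, 1172.0),
        }
    )
    return EpochSet(
        data=data,
        time_ms=t0 + 4.0 * np.arange(n_times),
        channel_names=[f"CH{i}" for i in range(n_channels)],
        trials=trials,
    )


@pytest.fixture(scope="session")
def small_design():
    return Design(n_short=24, n_early=16, n_late=16, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_epochs(small_design)


@pytest.fixture(scope="session")
def small_participant():
    """One preprocessed simulated participant at desk scale (shared)."""
    return prepare_participant(Design(n_short=0, n_early=60, n_late=60, seed=11))
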