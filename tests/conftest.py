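import numpy as np
import pytest

from laminarlfp import synth
from laminarlfp.decompose import run_ica
from laminarlfp.io import EventTable, LaminarRecording


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic session shared across tests (10 trials, 500 Hz)."""
    return synth.generate_dataset(n_trials=10, fs=500.0, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """One session at the default study conditions (18 trials, 1 kHz)."""
    return synth.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_decomposition(default_dataset):
    return run_ica(default_dataset["recording"], seed=0)


@pytest.fixture()
def toy_recording():
    rng = np.random.default_rng(0)
    samples = rng.standard_normal((8, 1000))
    depths = np.arange(100.0, 1151.0, 150.0)
    return LaminarRecording(samples=samples, depths=depths, fs=1000.0)


@pytest.fixture()
def toy_events():
    return EventTable(pull_onsets=np.array([2.0, 5.0, 8.0]))
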