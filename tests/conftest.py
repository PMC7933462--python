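import numpy as np
import pytest

from eumotion import EEGTrial, GeneratorConfig, OFFLINE_MONTAGE
from eumotion.synth import generate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sine_trial():
    """Unit-amplitude 10 Hz sinusoid on all 14 offline channels, 10 s at 128 Hz."""
    fs = 128.0
    t = np.arange(int(10 * fs)) / fs
    sig = np.sin(2 * np.pi * 10.0 * t)
    data = np.tile(sig, (14, 1))
    return EEGTrial(data, fs, list(OFFLINE_MONTAGE.channels))


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects x 10 short trials, in memory; shared across tests."""
    cfg = GeneratorConfig(n_subjects=3, trials_per_subject=10,
                          trial_duration_s=15.0, seed=11)
    return cfg, generate_trials(cfg)
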