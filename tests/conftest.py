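import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alphaconn import (
    CouplingPair,
    EpochSet,
    Recording,
    SimConfig,
    simulate_recording,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ten_second_recording():
    """4-channel white-noise recording, 10 s at 100 Hz."""
    g = np.random.default_rng(0)
    return Recording(
        samples=g.standard_normal((4, 1000)),
        fs=100.0,
        channel_labels=[f"ch{i:03d}" for i in range(4)],
    )


@pytest.fixture
def coupled_recording():
    """Strong pi/2-lag coupling between channels 0 and 1 at 7.5 Hz."""
    cfg = SimConfig(
        n_channels=4,
        duration=110.0,
        fs=500.0,
        coupling_pairs=(CouplingPair(0, 1, 7.5, np.pi / 2, 1.0),),
        snr=np.inf,
        seed=7,
    )
    return simulate_recording(cfg)


def white_noise_epochs(n_epochs, n_channels, n_samples=500, fs=500.0, seed=0):
    g = np.random.default_rng(seed)
    return EpochSet(
        epochs=g.standard_normal((n_epochs, n_channels, n_samples)),
        fs=fs,
        epoch_length=n_samples / fs,
        overlap=0.5,
        channel_labels=[f"ch{i:03d}" for i in range(n_channels)],
    )
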