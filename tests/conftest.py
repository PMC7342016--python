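import numpy as np
import pytest

from oscdecode.epochs import EpochSet
from oscdecode.simulate import SimConfig, generate_participant


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small, fast generation settings used across unit tests."""
    return SimConfig(
        n_participants=2,
        n_channels=8,
        n_objects=4,
        trials_per_object_per_task=8,
        sampling_rate=200.0,
        perception_window=(-600.0, 900.0),
        imagery_window=(-600.0, 1400.0),
        perception_latency=(200.0, 600.0),
        imagery_latency=(400.0, 1100.0),
        snr=2.0,
        posterior_fraction=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_participant(tiny_config):
    return generate_participant(tiny_config, 0)


def make_epochs(
    n_trials=6,
    n_channels=3,
    sfreq=200.0,
    tmin=-600.0,
    tmax=900.0,
    task="perception",
    n_objects=3,
    rng=None,
    data=None,
):
    """Hand-rolled EpochSet helper for tests that need full control."""
    n_times = int(round((tmax - tmin) / 1000.0 * sfreq))
    times = tmin + np.arange(n_times) * 1000.0 / sfreq
    if data is None:
        rng = rng or np.random.default_rng(0)
        data = rng.standard_normal((n_trials, n_channels, n_times))
    objs = (np.arange(n_trials) % n_objects) + 1
    return EpochSet(
        data=data,
        task=np.array([task] * n_trials),
        object_id=objs,
        times=times,
        channels=[f"CH{i:02d}" for i in range(n_channels)],
        sampling_rate=sfreq,
    )
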