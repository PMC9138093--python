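import numpy as np
import pandas as pd
import pytest

from neuropref.spectral import BandPowerTable
from neuropref.synthgen import CHANNELS, EEGEpoch, SAMPLING_RATE, SynthConfig, make_dataset

BANDS = ("theta", "alpha", "beta", "gamma")
ELECTRODES = ("F3", "F4", "AF3", "AF4")


def make_bp(default: float = 2.0, **overrides) -> BandPowerTable:
    """Band-power table from keyword overrides like alpha_F4=3.0."""
    df = pd.DataFrame(default, index=list(ELECTRODES), columns=list(BANDS), dtype=float)
    for key, value in overrides.items():
        band, el = key.split("_", 1)
        df.loc[el, band] = value
    return BandPowerTable(df)


def tone_epoch(freq: float, amplitude: float = 1.0, n_samples: int = 512,
               channel: str | None = None, label: str = "like") -> EEGEpoch:
    """Epoch whose channels carry a pure sinusoid (all channels, or just one)."""
    t = np.arange(n_samples) / SAMPLING_RATE
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    signal = np.zeros((len(CHANNELS), n_samples))
    if channel is None:
        signal[:] = tone
    else:
        signal[CHANNELS.index(channel)] = tone
    return EEGEpoch(signal=signal, channel_names=CHANNELS, fs=SAMPLING_RATE,
                    label=label, subject_id=0, trial_id=0)


def zero_epoch(n_samples: int = 512) -> EEGEpoch:
    return EEGEpoch(signal=np.zeros((len(CHANNELS), n_samples)), channel_names=CHANNELS,
                    fs=SAMPLING_RATE, label="like", subject_id=0, trial_id=0)


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    return SynthConfig(n_subjects=3, n_trials_per_subject=8, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return make_dataset(tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
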