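"""Synthetic EEG generator emulating a like/dislike neuromarketing study.

The generator reproduces the design of a 14-channel consumer-preference
experiment: 25 subjects, 42 product-viewing trials each, Emotiv EPOC+ montage,
128 Hz sampling, 4-45 Hz band-limited activity. Each epoch is a sum of
band-limited oscillations (theta, alpha, beta, gamma) plus 1/f pink noise.
A controllable asymmetry factor ``delta`` plants the frontal alpha/beta
asymmetry that distinguishes "like" from "dislike": for liked stimuli the
left frontal alpha (AF3/F3) is attenuated and the right (AF4/F4) amplified,
with the mirror-image scaling applied to beta, so approach/withdrawal and
valence indices are positive in expectation for "like". Non-frontal channels
carry no class effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Emotiv EPOC+ 10-20 montage, in headset order.
CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Frontal electrodes carrying the planted class effect.
LEFT_FRONTAL = ("AF3", "F3")
RIGHT_FRONTAL = ("AF4", "F4")
FRONTAL = LEFT_FRONTAL + RIGHT_FRONTAL

LIKE, DISLIKE = "like", "dislike"

SAMPLING_RATE = 128

#: Oscillation bands (Hz); gamma is capped at the 45 Hz band-pass ceiling.
BAND_RANGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

_SINUSOIDS_PER_BAND = 3


@dataclass
class EEGEpoch:
    """One trial's multi-channel EEG segment.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts (arbitrary scale).
    channel_names : sequence of str
        Ordered 10-20 labels; must contain the four frontal electrodes.
    fs : int
        Sampling rate in Hz.
    label : str
        ``"like"`` or ``"dislike"``.
    """

    signal: np.ndarray
    channel_names: tuple[str, ...]
    fs: int
    label: str
    subject_id: int
    trial_id: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_names):
            raise ValueError("signal must be channels x samples, aligned with channel_names")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.label not in (LIKE, DISLIKE):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by 10-20 name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.signal[idx]

    @property
    def label_int(self) -> int:
        """Binary label, like=1 / dislike=0."""
        return int(self.label == LIKE)


def _default_band_amplitudes() -> dict[str, float]:
    # Rough resting-EEG proportions: alpha dominant, gamma weakest (uV).
    return {"theta": 4.0, "alpha": 6.0, "beta": 3.0, "gamma": 1.5}


@dataclass
class SynthConfig:
    """Configuration of the synthetic study.

    ``asymmetry_effect`` (delta, in [0, 1)) scales the class-dependent
    left/right amplitude difference of alpha and beta at the frontal
    electrodes; delta=0 makes the two classes identically distributed.
    """

    n_subjects: int = 25
    n_trials_per_subject: int = 42
    epoch_seconds: float = 4.0
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    asymmetry_effect: float = 0.5
    pink_noise_sd: float = 5.0
    subject_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("n_subjects and n_trials_per_subject must be >= 1")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if not (0.0 <= self.asymmetry_effect < 1.0):
            raise ValueError("asymmetry_effect must lie in [0, 1)")
        unknown = set(self.band_amplitudes) - set(BAND_RANGES)
        if unknown:
            raise ValueError(f"unknown bands in band_amplitudes: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * SAMPLING_RATE))

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class LabeledEpochSet:
    """Ordered epochs with an aligned binary label vector (like=1)."""

    epochs: list[EEGEpoch]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.epochs) != len(self.labels):
            raise ValueError("epochs and labels lengths differ")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spectrum * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _subject_jitter(config: SynthConfig, subject_id: int) -> dict[str, float]:
    """Per-subject multiplicative log-normal amplitude jitter, seed-stable."""
    rng = np.random.default_rng((config.seed, subject_id, 0xA5))
    return {
        band: float(np.exp(rng.normal(0.0, config.subject_sd)))
        for band in BAND_RANGES
    }


def _class_factor(band: str, channel: str, label: str, delta: float) -> float:
    if channel not in FRONTAL or band not in ("alpha", "beta"):
        return 1.0
    left = channel in LEFT_FRONTAL
    # like: alpha left*(1-d) right*(1+d); beta mirrored. dislike reverses.
    sign = -1.0 if left else 1.0
    if band == "beta":
        sign = -sign
    if label == DISLIKE:
        sign = -sign
    return 1.0 + sign * delta


def make_epoch(
    config: SynthConfig, subject_id: int, label: str, rng: np.random.Generator
) -> EEGEpoch:
    """Draw one synthetic epoch for a subject under a given preference label.

    Each channel is a sum over the four bands of ``_SINUSOIDS_PER_BAND``
    sinusoids with frequencies uniform in the band and uniform phases, plus
    pink noise. Frontal alpha/beta amplitudes carry the class effect.
    """
    if label not in (LIKE, DISLIKE):
        raise ValueError(f"unknown label {label!r}")
    n = config.n_samples
    if n <= 0:
        raise ValueError("non-positive epoch length")
    t = np.arange(n) / SAMPLING_RATE
    jitter = _subject_jitter(config, subject_id)
    signal = np.empty((len(CHANNELS), n))
    for ci, channel in enumerate(CHANNELS):
        x = np.zeros(n)
        for band, (lo, hi) in BAND_RANGES.items():
            amp = config.band_amplitudes.get(band, 0.0) * jitter[band]
            amp *= _class_factor(band, channel, label, config.asymmetry_effect)
            amp /= _SINUSOIDS_PER_BAND
            freqs = rng.uniform(lo, hi, _SINUSOIDS_PER_BAND)
            phases = rng.uniform(0.0, 2.0 * np.pi, _SINUSOIDS_PER_BAND)
            x += amp * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
        x += config.pink_noise_sd * _pink_noise(n, rng)
        signal[ci] = x
    return EEGEpoch(
        signal=signal,
        channel_names=CHANNELS,
        fs=SAMPLING_RATE,
        label=label,
        subject_id=subject_id,
        trial_id=-1,
    )


def _subject_labels(config: SynthConfig, subject_id: int) -> list[str]:
    """Seed-deterministic like/dislike sequence for one subject.

    The like proportion is Beta(5,5) clipped to [0.2, 0.8]; with >= 2 trials
    both classes are guaranteed present.
    """
    rng = np.random.default_rng((config.seed, subject_id, 0xB7))
    n = config.n_trials_per_subject
    p_like = float(np.clip(rng.beta(5.0, 5.0), 0.2, 0.8))
    n_like = int(round(p_like * n))
    if n >= 2:
        n_like = min(max(n_like, 1), n - 1)
    labels = [LIKE] * n_like + [DISLIKE] * (n - n_like)
    rng.shuffle(labels)
    return labels


def make_dataset(config: SynthConfig) -> LabeledEpochSet:
    """Generate the full study: n_subjects x n_trials_per_subject epochs.

    Deterministic given (config, seed): every epoch draws from its own
    RNG stream keyed on (seed, subject, trial).
    """
    epochs: list[EEGEpoch] = []
    labels: list[int] = []
    for subject_id in range(config.n_subjects):
        for trial_id, label in enumerate(_subject_labels(config, subject_id)):
            rng = np.random.default_rng((config.seed, subject_id, trial_id))
            epoch = make_epoch(config, subject_id, label, rng)
            epoch.trial_id = trial_id
            epochs.append(epoch)
            labels.append(epoch.label_int)
    return LabeledEpochSet(epochs=epochs, labels=np.asarray(labels))


# ---------------------------------------------------------------------------
# plain-text round trip

def write_epochs(dataset: LabeledEpochSet, signals_path, labels_path) -> None:
    """Write a dataset as two delimited text files.

    ``signals_path``: long format, columns subject,trial,channel,sample,value.
    ``labels_path``: columns subject,trial,label.
    """
    frames = []
    for ep in dataset.epochs:
        n_ch, n_s = ep.signal.shape
        frames.append(pd.DataFrame({
            "subject": ep.subject_id,
            "trial": ep.trial_id,
            "channel": np.repeat(list(ep.channel_names), n_s),
            "sample": np.tile(np.arange(n_s), n_ch),
            "value": ep.signal.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(signals_path, index=False)
    pd.DataFrame({
        "subject": [ep.subject_id for ep in dataset.epochs],
        "trial": [ep.trial_id for ep in dataset.epochs],
        "label": [ep.label for ep in dataset.epochs],
    }).to_csv(labels_path, index=False)


def read_epochs(signals_path, labels_path, fs: int = SAMPLING_RATE) -> LabeledEpochSet:
    """Inverse of :func:`write_epochs`; epoch order follows the labels file."""
    sig = pd.read_csv(signals_path)
    lab = pd.read_csv(labels_path)
    grouped = {k: g for k, g in sig.groupby(["subject", "trial"], sort=False)}
    epochs = []
    for _, row in lab.iterrows():
        g = grouped[(row["subject"], row["trial"])]
        pivot = g.pivot(index="channel", columns="sample", values="value")
        channel_names = [c for c in CHANNELS if c in pivot.index] or list(pivot.index)
        epochs.append(EEGEpoch(
            signal=pivot.loc[channel_names].to_numpy(),
            channel_names=tuple(channel_names),
            fs=fs,
            label=row["label"],
            subject_id=int(row["subject"]),
            trial_id=int(row["trial"]),
        ))
    labels = np.array([ep.label_int for ep in epochs])
    return LabeledEpochSet(epochs=epochs, labels=labels)
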