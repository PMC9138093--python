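"""Spectral feature extraction for preference epochs.

All features derive from the four preference-relevant frontal electrodes
(F3, F4, AF3, AF4): a 257-bin one-sided FFT power spectral density per
channel (512-point transform at 128 Hz), its cross-channel sum and average,
a 61-point Morlet time-frequency average power (4-45 Hz), a 65-row Hann
spectrogram time-average, and the ten preference indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthgen import EEGEpoch, LabeledEpochSet, SAMPLING_RATE

#: Electrodes feeding the preference indices, in feature-block order.
FRONTAL_ELECTRODES = ("F3", "F4", "AF3", "AF4")

#: Band edges in Hz. Intervals are half-open [low, high); the top band
#: (gamma) additionally includes its upper edge, the 45 Hz band-pass ceiling.
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

NFFT = 512
MORLET_N_FREQS = 61
MORLET_FMIN, MORLET_FMAX = 4.0, 45.0
MORLET_N_CYCLES = 7
SPECTROGRAM_NPERSEG = 128

#: Floor applied to band powers before they feed ratios and logarithms.
POWER_EPS = 1e-12


@dataclass
class PSDMatrix:
    """One-sided power spectral density per channel.

    ``values[i, j]`` is the PSD of ``channel_names[i]`` at ``freqs[j]``,
    normalized so that ``sum(values) * df`` equals the mean squared signal
    (Parseval convention).
    """

    values: np.ndarray
    freqs: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (len(self.channel_names), len(self.freqs)):
            raise ValueError("values shape must be (n_channels, n_freqs)")
        if np.any(self.values < 0):
            raise ValueError("PSD values must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class BandPowerTable:
    """Average band power per frontal electrode x band."""

    power: pd.DataFrame  # index: electrodes, columns: bands

    def get(self, electrode: str, band: str) -> float:
        if electrode not in self.power.index:
            raise KeyError(f"unknown electrode {electrode!r}")
        if band not in self.power.columns:
            raise KeyError(f"unknown band {band!r}")
        return float(self.power.loc[electrode, band])


@dataclass
class FeatureVector:
    """Named feature vector with queryable block boundaries."""

    names: tuple[str, ...]
    values: np.ndarray
    blocks: dict[str, slice]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def block(self, name: str) -> np.ndarray:
        return self.values[self.blocks[name]]


def psd_fft(
    epoch: EEGEpoch,
    channels: tuple[str, ...] = FRONTAL_ELECTRODES,
    nfft: int = NFFT,
) -> PSDMatrix:
    """One-sided periodogram PSD, ``nfft/2 + 1`` bins per requested channel.

    Signals shorter than ``nfft`` are zero-padded; the default 512-point
    transform of a 4 s epoch at 128 Hz yields 257 bins per channel.
    """
    rows = []
    for name in channels:
        x = epoch.channel(name)
        if x.size == 0:
            raise ValueError("empty signal")
        if x.size > nfft:
            raise ValueError(f"epoch has {x.size} samples; nfft={nfft} would truncate")
        freqs, pxx = sps.periodogram(
            x, fs=epoch.fs, window="boxcar", nfft=nfft, scaling="density"
        )
        rows.append(pxx)
    return PSDMatrix(values=np.asarray(rows), freqs=freqs, channel_names=tuple(channels))


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    mask = (freqs >= low) & (freqs < high)
    if high >= max(h for _, h in BANDS.values()):  # top band keeps its ceiling bin
        mask |= freqs == high
    return mask


def band_power(psd: PSDMatrix, electrode: str, band) -> float:
    """Mean PSD over a named band or an explicit ``(low, high)`` range.

    Floored at ``POWER_EPS`` so downstream logarithms stay finite.
    """
    if isinstance(band, str):
        try:
            low, high = BANDS[band]
        except KeyError:
            raise KeyError(f"unknown band {band!r}") from None
    else:
        low, high = band
    nyquist = psd.freqs[-1]
    if low < 0 or high > nyquist:
        raise ValueError(f"band [{low}, {high}] outside [0, {nyquist}] Hz")
    values = psd.channel(electrode)[_band_mask(psd.freqs, low, high)]
    return max(float(values.mean()), POWER_EPS)


def band_power_table(epoch: EEGEpoch) -> BandPowerTable:
    """Frontal electrode x band average-power table for one epoch."""
    psd = psd_fft(epoch)
    data = {
        band: [band_power(psd, el, band) for el in FRONTAL_ELECTRODES]
        for band in BANDS
    }
    return BandPowerTable(pd.DataFrame(data, index=list(FRONTAL_ELECTRODES)))


def _morlet_grid() -> np.ndarray:
    return np.linspace(MORLET_FMIN, MORLET_FMAX, MORLET_N_FREQS)


def _morlet_power_batch(signals: np.ndarray, fs: float) -> np.ndarray:
    """Time-averaged Morlet power, batched over (n_epochs, n_channels, n_times)."""
    from mne.time_frequency import tfr_array_morlet

    power = tfr_array_morlet(
        signals, sfreq=fs, freqs=_morlet_grid(),
        n_cycles=MORLET_N_CYCLES, output="power", verbose="error",
    )
    return power.mean(axis=-1)


def morlet_avg_power(epoch: EEGEpoch, electrode: str) -> np.ndarray:
    """Time-averaged complex-Morlet power at 61 frequencies spanning 4-45 Hz."""
    x = epoch.channel(electrode)
    return _morlet_power_batch(x[None, None, :], epoch.fs)[0, 0]


def spectrogram_hann(epoch: EEGEpoch, electrode: str) -> np.ndarray:
    """Time-averaged Hann spectrogram rows: 128-sample segments, 50% overlap.

    Yields 65 (= 128/2 + 1) features per channel.
    """
    x = epoch.channel(electrode)
    if x.size < SPECTROGRAM_NPERSEG:
        raise ValueError(
            f"epoch has {x.size} samples; spectrogram needs >= {SPECTROGRAM_NPERSEG}"
        )
    _, _, sxx = sps.spectrogram(
        x, fs=epoch.fs, window="hann",
        nperseg=SPECTROGRAM_NPERSEG, noverlap=SPECTROGRAM_NPERSEG // 2,
    )
    return sxx.mean(axis=1)


# ---------------------------------------------------------------------------
# feature assembly

def _index_feature_names() -> list[str]:
    from .indices import INDEX_NAMES

    return [f"index_{name}" for name in INDEX_NAMES]


def assemble_features(epoch: EEGEpoch) -> FeatureVector:
    """Concatenate all spectral blocks and the ten preference indices.

    Blocks, in order: per-channel 257-bin PSD (x4), cross-channel PSD sum and
    average (257 each), per-channel Morlet 61 (x4), per-channel spectrogram
    65 (x4), preference indices (10) — 2,056 features total. Boundaries are
    recorded in ``FeatureVector.blocks``.
    """
    from .indices import compute_indices

    psd = psd_fft(epoch)
    names: list[str] = []
    chunks: list[np.ndarray] = []
    blocks: dict[str, slice] = {}

    def add(block: str, block_names: list[str], values: np.ndarray) -> None:
        start = len(names)
        names.extend(block_names)
        chunks.append(np.asarray(values, dtype=float))
        blocks[block] = slice(start, len(names))

    n_bins = len(psd.freqs)
    for el in FRONTAL_ELECTRODES:
        add(f"psd_{el}", [f"psd_{el}_b{i:03d}" for i in range(n_bins)], psd.channel(el))
    add("psd_sum", [f"psd_sum_b{i:03d}" for i in range(n_bins)], psd.values.sum(axis=0))
    add("psd_avg", [f"psd_avg_b{i:03d}" for i in range(n_bins)], psd.values.mean(axis=0))
    for el in FRONTAL_ELECTRODES:
        add(
            f"morlet_{el}",
            [f"morlet_{el}_m{i:02d}" for i in range(MORLET_N_FREQS)],
            morlet_avg_power(epoch, el),
        )
    for el in FRONTAL_ELECTRODES:
        n_rows = SPECTROGRAM_NPERSEG // 2 + 1
        add(
            f"spec_{el}",
            [f"spec_{el}_s{i:02d}" for i in range(n_rows)],
            spectrogram_hann(epoch, el),
        )
    idx = compute_indices(band_power_table(epoch))
    add("indices", _index_feature_names(), idx.to_array())
    return FeatureVector(names=tuple(names), values=np.concatenate(chunks), blocks=blocks)


def index_feature_table(dataset: LabeledEpochSet) -> pd.DataFrame:
    """Fast path: subject/trial/label plus the ten index features per epoch."""
    from .indices import compute_indices

    rows = []
    for ep in dataset.epochs:
        idx = compute_indices(band_power_table(ep))
        rows.append([ep.subject_id, ep.trial_id, ep.label_int, *idx.to_array()])
    cols = ["subject", "trial", "label"] + _index_feature_names()
    return pd.DataFrame(rows, columns=cols)


def full_feature_table(dataset: LabeledEpochSet) -> pd.DataFrame:
    """All 2,056 features per epoch (slow path; indices-only extraction is
    usually what a benchmark at scale wants, see :func:`index_feature_table`)."""
    vectors = [assemble_features(ep) for ep in dataset.epochs]
    df = pd.DataFrame(np.vstack([fv.values for fv in vectors]),
                      columns=list(vectors[0].names))
    df.insert(0, "label", [ep.label_int for ep in dataset.epochs])
    df.insert(0, "trial", [ep.trial_id for ep in dataset.epochs])
    df.insert(0, "subject", [ep.subject_id for ep in dataset.epochs])
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Delimited-text feature table: subject/trial/label + named features."""
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
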