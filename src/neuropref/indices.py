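"""Frontal preference indices.

Ten scalar indices summarizing frontal band-power asymmetry between the left
(AF3, F3) and right (AF4, F4) hemisphere, grouped in the neuromarketing
literature as approach/withdrawal (alpha asymmetry), valence (four variants),
choice likelihood (beta/gamma log asymmetry) and cognitive effort (theta
asymmetry). All are computed from a :class:`~neuropref.spectral.BandPowerTable`.

Two-electrode arguments such as ``alpha(AF4, F4)`` denote the arithmetic mean
of the band power at the two electrodes (see :func:`pair_power`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import BandPowerTable

INDEX_NAMES = (
    "touchette_aw",
    "aw",
    "vamv_valence",
    "kirk_valence",
    "ram12_valence",
    "ram15_valence",
    "choice_gamma",
    "choice_beta",
    "effort_1",
    "effort_2",
)

#: Threshold below which a choice-index denominator is flagged as unstable.
DENOM_WARN = 1e-9


@dataclass
class PreferenceIndices:
    """The ten preference indices for one epoch, all unitless."""

    touchette_aw: float
    aw: float
    vamv_valence: float
    kirk_valence: float
    ram12_valence: float
    ram15_valence: float
    choice_gamma: float
    choice_beta: float
    effort_1: float
    effort_2: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in INDEX_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def pair_power(bp: BandPowerTable, band: str, pair: tuple[str, str]) -> float:
    """Arithmetic mean of a band's power at two electrodes."""
    a, b = pair
    return 0.5 * (bp.get(a, band) + bp.get(b, band))


def _choice(bp: BandPowerTable, band: str) -> float:
    """Frontal log-power asymmetry of a band at AF3 vs AF4.

    The ratio structure makes the value independent of the logarithm base;
    natural log is used. The denominator changes sign when a power crosses
    1.0, so near-zero denominators are flagged with a warning rather than
    clipped.
    """
    left = np.log(bp.get("AF3", band))
    right = np.log(bp.get("AF4", band))
    denom = left + right
    if abs(denom) < DENOM_WARN:
        warnings.warn(
            f"choice index denominator |log {band}(AF3) + log {band}(AF4)| "
            f"= {abs(denom):.3g} is near zero; index is numerically unstable",
            RuntimeWarning,
            stacklevel=3,
        )
    return (left - right) / denom


def compute_indices(bp: BandPowerTable) -> PreferenceIndices:
    """Evaluate all ten indices from positive band powers.

    Raises ``ValueError`` if any required entry is non-positive (powers are
    floored upstream; a non-positive value signals an upstream fault).
    """
    for el in ("F3", "F4", "AF3", "AF4"):
        for band in ("theta", "alpha", "beta", "gamma"):
            if bp.get(el, band) <= 0:
                raise ValueError(f"non-positive band power {band}({el})")

    alpha_l = pair_power(bp, "alpha", ("AF3", "F3"))
    alpha_r = pair_power(bp, "alpha", ("AF4", "F4"))
    beta_l = pair_power(bp, "beta", ("AF3", "F3"))
    beta_r = pair_power(bp, "beta", ("AF4", "F4"))
    theta_l = pair_power(bp, "theta", ("AF3", "F3"))
    theta_r = pair_power(bp, "theta", ("AF4", "F4"))

    a_f3, a_f4 = bp.get("F3", "alpha"), bp.get("F4", "alpha")
    b_f3, b_f4 = bp.get("F3", "beta"), bp.get("F4", "beta")
    t_f3, t_f4 = bp.get("F3", "theta"), bp.get("F4", "theta")

    return PreferenceIndices(
        touchette_aw=(a_f4 - a_f3) / (a_f4 + a_f3),
        aw=alpha_r - alpha_l,
        vamv_valence=beta_l / alpha_l - beta_r / alpha_r,
        kirk_valence=float(np.log(alpha_l) - np.log(alpha_r)),
        ram12_valence=a_f4 - b_f3,
        ram15_valence=a_f4 / b_f4 - a_f3 / b_f3,
        choice_gamma=_choice(bp, "gamma"),
        choice_beta=_choice(bp, "beta"),
        effort_1=(t_f4 - t_f3) / (t_f4 + t_f3),
        effort_2=theta_r - theta_l,
    )


def write_index_table(df, path) -> None:
    """One row per trial: subject, trial, label and the ten named indices."""
    df.to_csv(path, index=False)
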