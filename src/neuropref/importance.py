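"""Univariate importance diagnostics: ANOVA F and Kendall tau-b.

These accompany the multivariate selectors: the one-way F statistic screens
each feature for a like/dislike mean difference, and the tie-corrected
Kendall tau-b matrix shows the rank agreement among the top features and the
class label (the label is encoded like=1 / dislike=0, so a positive tau means
larger feature values with liked stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif

from .selection import FeatureTable

LABEL_COLUMN = "label"


@dataclass
class CorrelationMatrix:
    """Symmetric Kendall tau-b matrix over features (and the label)."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def anova_f(table: FeatureTable) -> np.ndarray:
    """One-way two-group F statistic per feature.

    F is the between-group mean square over the within-group mean square; in
    the two-group case it equals the squared pooled-variance t statistic.
    """
    classes, counts = np.unique(table.labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("both classes need >= 2 trials")
    f_stats, _ = f_classif(table.matrix, table.labels)
    return np.nan_to_num(f_stats, nan=0.0)


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation (tau-b), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both inputs have zero variance")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def correlation_heatmap_table(
    table: FeatureTable, features: list[str]
) -> CorrelationMatrix:
    """Pairwise tau-b over the requested features plus the binary label."""
    missing = [f for f in features if f not in table.feature_names]
    if missing:
        raise KeyError(f"unknown features: {missing}")
    columns = [table.matrix[:, table.feature_names.index(f)] for f in features]
    columns.append(table.labels.astype(float))
    names = list(features) + [LABEL_COLUMN]
    n = len(names)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kendall_tau(columns[i], columns[j])
    return CorrelationMatrix(names=names, values=values)


def plot_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the tau-b matrix as an annotated heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(matrix.names),) * 2)
    sns.heatmap(
        matrix.to_frame(), annot=True, fmt=".2f", cmap="vlag",
        vmin=-1, vmax=1, square=True, ax=ax,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
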