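"""Feature selection for like/dislike EEG feature tables.

Four selectors are provided: greedy minimum-redundancy-maximum-relevance
(mRMR, with the mutual-information difference MID and quotient MIQ schemes),
ReliefF nearest-hit/miss weighting, recursive feature elimination driven by
random-forest importance (RF-RFE), and PCA as an unsupervised transformer.
All are deterministic given (table, parameters, seed); ties break by
ascending original feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

DEFAULT_MI_BINS = 3
DEFAULT_RELIEFF_NEIGHBORS = 10
DEFAULT_RF_TREES = 500
DEFAULT_RFE_STEP = 0.1
DEFAULT_RFE_SELECT = 10

_META_COLUMNS = ("subject", "trial", "label")


@dataclass
class FeatureTable:
    """Trials x features matrix with names and a binary label vector."""

    matrix: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = list(self.feature_names)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (trials x features)")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix entries must be finite")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "FeatureTable":
        """Build from a delimited-text style frame; subject/trial columns are
        treated as metadata, everything else as features."""
        feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
        return cls(
            matrix=df[feature_cols].to_numpy(dtype=float),
            feature_names=feature_cols,
            labels=df[label_col].to_numpy(dtype=int),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df

    def subset(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.matrix[:, idx], list(names), self.labels)

    def rows(self, index: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.matrix[index], self.feature_names, self.labels[index])


@dataclass
class SelectionResult:
    """Ordered selected features with per-feature criterion scores."""

    method: str
    selected: list[str]
    scores: np.ndarray
    k: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.selected) != len(self.scores):
            raise ValueError("selected and scores lengths differ")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate selected features")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.selected) + 1),
            "feature": self.selected,
            "score": self.scores,
            "method": self.method,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mutual information and mRMR

def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mi_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two integer code vectors."""
    nx, ny = cx.max() + 1, cy.max() + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_info(x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> float:
    """MI between a numeric feature and a discrete label, in bits.

    The feature is discretized by equal-frequency binning (default 3 bins);
    the label's distinct values are used directly. Non-negative by
    construction; zero-probability cells are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cy = np.unique(y, return_inverse=True)[1]
    return _mi_codes(_discretize(x, n_bins), cy)


def mrmr_rank(
    table: FeatureTable,
    k: int,
    scheme: str = "MIQ",
    n_bins: int = DEFAULT_MI_BINS,
) -> SelectionResult:
    """Greedy minimum-redundancy-maximum-relevance selection.

    The first pick maximizes relevance I(x; y). With q features already
    chosen, candidates maximize ``I(x;y) - mean_b I(x;x_b)`` (MID) or
    ``I(x;y) / mean_b I(x;x_b)`` (MIQ, default). Feature-feature MI uses the
    same discretization as feature-label MI and is cached pairwise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.n_features < 2:
        raise ValueError("need at least two features")
    scheme = scheme.upper()
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    if k > table.n_features:
        warnings.warn(
            f"k={k} exceeds feature count {table.n_features}; clamping",
            UserWarning, stacklevel=2,
        )
        k = table.n_features

    p = table.n_features
    codes = np.column_stack([_discretize(table.matrix[:, j], n_bins) for j in range(p)])
    y_codes = np.unique(table.labels, return_inverse=True)[1]
    relevance = np.array([_mi_codes(codes[:, j], y_codes) for j in range(p)])

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    while len(selected) < k:
        if not selected:
            criterion = relevance.copy()
        else:
            redundancy = red_sum / len(selected)
            if scheme == "MID":
                criterion = relevance - redundancy
            else:
                criterion = relevance / np.maximum(redundancy, 1e-12)
        criterion = np.where(available, criterion, -np.inf)
        pick = int(np.argmax(criterion))  # argmax -> lowest index on ties
        selected.append(pick)
        scores.append(float(criterion[pick]))
        available[pick] = False
        red_sum[available] += [
            _mi_codes(codes[:, j], codes[:, pick]) for j in np.flatnonzero(available)
        ]
    return SelectionResult(
        method=f"mrmr_{scheme.lower()}",
        selected=[table.feature_names[j] for j in selected],
        scores=np.asarray(scores),
        k=k,
    )


# ---------------------------------------------------------------------------
# ReliefF

def relieff_weights(
    table: FeatureTable, n_neighbors: int = DEFAULT_RELIEFF_NEIGHBORS
) -> np.ndarray:
    """ReliefF feature weights over all instances.

    Features are min-max normalized internally; neighbours are found with the
    Manhattan metric. For every instance the weight of feature f decreases by
    the mean |diff| to its nearest hits and increases by the class-prior
    weighted mean |diff| to the nearest misses of each other class, averaged
    over instances, giving weights in [-1, 1].
    """
    X, y = table.matrix, table.labels
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts <= n_neighbors):
        raise ValueError(f"every class needs > {n_neighbors} members")
    priors = counts / n

    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0  # constant feature -> diff stays 0
    Z = (X - X.min(axis=0)) / span

    dist = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    weights = np.zeros(p)
    for i in range(n):
        same = y == y[i]
        hit_idx = np.flatnonzero(same)
        hit_idx = hit_idx[np.argsort(dist[i, hit_idx], kind="stable")[:n_neighbors]]
        weights -= np.abs(Z[hit_idx] - Z[i]).sum(axis=0) / (n * n_neighbors)
        p_self = priors[classes == y[i]][0]
        for c, p_c in zip(classes, priors):
            if c == y[i]:
                continue
            miss_idx = np.flatnonzero(y == c)
            miss_idx = miss_idx[np.argsort(dist[i, miss_idx], kind="stable")[:n_neighbors]]
            w_c = p_c / (1.0 - p_self)
            weights += w_c * np.abs(Z[miss_idx] - Z[i]).sum(axis=0) / (n * n_neighbors)
    return weights


def relieff_rank(
    table: FeatureTable, k: int, n_neighbors: int = DEFAULT_RELIEFF_NEIGHBORS
) -> SelectionResult:
    """Top-k features by ReliefF weight (ties to the lower original index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, table.n_features)
    weights = relieff_weights(table, n_neighbors=n_neighbors)
    order = np.argsort(-weights, kind="stable")[:k]
    return SelectionResult(
        method="relieff",
        selected=[table.feature_names[j] for j in order],
        scores=weights[order],
        k=k,
    )


# ---------------------------------------------------------------------------
# random-forest importance and RF-RFE

def rf_importance(
    table: FeatureTable, n_trees: int = DEFAULT_RF_TREES, seed: int = 0
) -> np.ndarray:
    """Impurity-decrease importances from a random forest; sum to 1."""
    if len(np.unique(table.labels)) < 2:
        raise ValueError("labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(table.matrix, table.labels)
    return forest.feature_importances_


def importance_rank(
    table: FeatureTable, k: int, n_trees: int = DEFAULT_RF_TREES, seed: int = 0
) -> SelectionResult:
    """Top-k features by random-forest importance."""
    k = min(k, table.n_features)
    imp = rf_importance(table, n_trees=n_trees, seed=seed)
    order = np.argsort(-imp, kind="stable")[:k]
    return SelectionResult(
        method="importance",
        selected=[table.feature_names[j] for j in order],
        scores=imp[order],
        k=k,
    )


def rfe_select(
    table: FeatureTable,
    n_select: int = DEFAULT_RFE_SELECT,
    step_fraction: float = DEFAULT_RFE_STEP,
    n_trees: int = DEFAULT_RF_TREES,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination with a random-forest ranker.

    Each round refits the forest on the surviving features and drops the
    ``ceil(step_fraction * remaining)`` lowest-importance ones (never past
    ``n_select``); survivors are returned ranked by their final importance.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > table.n_features:
        raise ValueError("n_select exceeds feature count")
    surviving = np.arange(table.n_features)
    while surviving.size > n_select:
        sub = FeatureTable(
            table.matrix[:, surviving],
            [table.feature_names[j] for j in surviving],
            table.labels,
        )
        imp = rf_importance(sub, n_trees=n_trees, seed=seed)
        n_drop = min(
            int(np.ceil(step_fraction * surviving.size)), surviving.size - n_select
        )
        drop = np.argsort(imp, kind="stable")[:n_drop]
        surviving = np.delete(surviving, drop)
    final = FeatureTable(
        table.matrix[:, surviving],
        [table.feature_names[j] for j in surviving],
        table.labels,
    )
    imp = rf_importance(final, n_trees=n_trees, seed=seed)
    order = np.argsort(-imp, kind="stable")
    return SelectionResult(
        method="rf_rfe",
        selected=[final.feature_names[j] for j in order],
        scores=imp[order],
        k=n_select,
    )


# ---------------------------------------------------------------------------
# PCA

def pca_transform(
    table: FeatureTable, n_components: int
) -> tuple[FeatureTable, np.ndarray]:
    """Project mean-centered features onto the leading principal components.

    Returns the transformed table (columns ``pc1..pcK``) and the explained
    variance ratios in non-increasing order. Sign convention: each
    component's largest-magnitude loading is positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(table.n_trials, table.n_features):
        raise ValueError("n_components exceeds min(n_trials, n_features)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(table.matrix)
    for j in range(n_components):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[j] = -comp
            scores[:, j] = -scores[:, j]
    names = [f"pc{j + 1}" for j in range(n_components)]
    return (
        FeatureTable(scores, names, table.labels),
        pca.explained_variance_ratio_.copy(),
    )
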