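"""Like/dislike classifier benchmark over feature-selection methods.

Five classifiers (1-NN, random forest with 500 trees, LDA, RBF-kernel SVM,
and a small multilayer perceptron trained with the hinge loss) are evaluated
on a stratified 80/20 holdout, with and without each feature selector. The
grid of accuracy / recall / precision / F-measure rows mirrors the standard
benchmark-table layout of preference-recognition studies.

The benchmark is leakage-safe by default: selectors and feature
standardization are fitted on the training partition only. A ``legacy`` mode
that fits selectors on the full table before splitting is provided for
comparison, since published pipelines are often ambiguous on this point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import (
    FeatureTable,
    SelectionResult,
    importance_rank,
    mrmr_rank,
    relieff_rank,
    rfe_select,
)

CLASSIFIER_KINDS = ("knn", "rf", "lda", "svm_rbf", "mlp_hinge")
SELECTOR_KINDS = ("none", "mrmr", "relieff", "rfe", "importance", "pca")

#: Classifiers whose features are z-scored with train statistics before the
#: fit; the random forest is scale-invariant and exempt.
_SCALED = {"knn", "lda", "svm_rbf", "mlp_hinge"}


class HingeMLP:
    """Two-hidden-layer perceptron trained with the hinge loss.

    Architecture 64-32 rectified units with a single linear output; labels
    are mapped to +/-1 and the mean margin loss max(0, 1 - y f(x)) is
    minimized with Adam. Training runs at most ``max_epochs`` full-batch
    epochs with early stopping on the training loss.
    """

    def __init__(
        self,
        hidden: tuple[int, int] = (64, 32),
        lr: float = 1e-3,
        max_epochs: int = 200,
        patience: int = 20,
        tol: float = 1e-5,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.seed = seed

    def _init_params(self, n_in: int, rng: np.random.Generator) -> list[np.ndarray]:
        sizes = [n_in, *self.hidden, 1]
        params = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            params.append(rng.normal(0.0, np.sqrt(2.0 / a), (a, b)))  # He init
            params.append(np.zeros(b))
        return params

    def _forward(self, X: np.ndarray, params: list[np.ndarray]):
        acts = [X]
        h = X
        n_layers = len(params) // 2
        for i in range(n_layers):
            w, b = params[2 * i], params[2 * i + 1]
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h[:, 0], acts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "HingeMLP":
        X = np.asarray(X, dtype=float)
        y_pm = np.where(np.asarray(y) > 0, 1.0, -1.0)
        rng = np.random.default_rng(self.seed)
        params = self._init_params(X.shape[1], rng)
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, stale = np.inf, 0
        n = X.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            f, acts = self._forward(X, params)
            margin = 1.0 - y_pm * f
            loss = float(np.maximum(margin, 0.0).mean())
            if loss < best_loss - self.tol:
                best_loss, stale = loss, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
            # backprop of the mean hinge loss
            grad_f = np.where(margin > 0, -y_pm, 0.0)[:, None] / n
            grads = [None] * len(params)
            delta = grad_f
            n_layers = len(params) // 2
            for i in range(n_layers - 1, -1, -1):
                a_prev = acts[i]
                grads[2 * i] = a_prev.T @ delta
                grads[2 * i + 1] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ params[2 * i].T) * (acts[i] > 0)
            for j, g in enumerate(grads):
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1**epoch)
                vhat = v[j] / (1 - beta2**epoch)
                params[j] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        self.params_ = params
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), self.params_)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


@dataclass
class ClassifierSpec:
    """One classifier configuration of the benchmark."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self):
        hp = self.hyperparameters
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 1))
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=hp.get("n_trees", 500), random_state=self.seed, n_jobs=1
            )
        if self.kind == "lda":
            return LinearDiscriminantAnalysis(n_components=hp.get("n_components", 1))
        if self.kind == "svm_rbf":
            return SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"))
        return HingeMLP(seed=self.seed, **hp)


@dataclass
class MetricRow:
    """One selector x classifier cell of the benchmark grid."""

    selector: str
    classifier: str
    accuracy: float
    recall: float
    precision: float
    f_measure: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "recall", "precision", "f_measure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def holdout_split(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split; disjoint, exhaustive, seed-deterministic."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    idx = np.arange(table.n_trials)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=table.labels
    )
    return table.rows(train_idx), table.rows(test_idx)


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    """Accuracy and class-frequency-weighted recall/precision/F.

    With weighted averaging the recall aggregate equals the accuracy; the
    F-measure is the harmonic mean of the weighted precision and recall.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    if np.any(cm < 0):
        raise ValueError("negative counts")
    total = cm.sum()
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall_c = np.where(support > 0, np.diag(cm) / support, 0.0)
        precision_c = np.where(predicted > 0, np.diag(cm) / predicted, 0.0)
    weights = support / total
    recall = float(weights @ recall_c)
    precision = float(weights @ precision_c)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "accuracy": float(np.trace(cm) / total),
        "recall": recall,
        "precision": precision,
        "f_measure": f,
    }


def train_eval(
    spec: ClassifierSpec, train: FeatureTable, test: FeatureTable
) -> MetricRow:
    """Fit one classifier on the train table and score it on the test table."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature names differ")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training labels contain a single class")
    X_train, X_test = train.matrix, test.matrix
    if spec.kind in _SCALED:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    model = spec.build().fit(X_train, train.labels)
    pred = model.predict(X_test)
    cm = confusion_matrix(test.labels, pred, labels=[0, 1])
    metrics = metrics_from_confusion(cm)
    return MetricRow(selector="", classifier=spec.kind, **metrics)


# ---------------------------------------------------------------------------
# selector fitting for the grid

class _NameSelector:
    def __init__(self, result: SelectionResult):
        self.result = result

    def apply(self, table: FeatureTable) -> FeatureTable:
        return table.subset(self.result.selected)


class _IdentitySelector:
    def apply(self, table: FeatureTable) -> FeatureTable:
        return table


class _PCASelector:
    """Train-fitted standardizer + PCA projection applied to any table."""

    def __init__(self, train: FeatureTable, n_components: int):
        from sklearn.decomposition import PCA

        self.mu = train.matrix.mean(axis=0)
        self.sd = train.matrix.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        n_components = min(n_components, train.n_trials, train.n_features)
        self.pca = PCA(n_components=n_components, svd_solver="full")
        self.pca.fit((train.matrix - self.mu) / self.sd)
        self.names = [f"pc{j + 1}" for j in range(n_components)]

    def apply(self, table: FeatureTable) -> FeatureTable:
        z = (table.matrix - self.mu) / self.sd
        return FeatureTable(self.pca.transform(z), self.names, table.labels)


def fit_selector(
    name: str, train: FeatureTable, k: int = 10, seed: int = 0, params: dict | None = None
):
    """Fit one selector on (what must be) the training partition."""
    params = dict(params or {})
    if name == "none":
        return _IdentitySelector()
    if name == "pca":
        return _PCASelector(train, n_components=params.pop("n_components", 1))
    k = min(k, train.n_features)
    if name == "mrmr":
        return _NameSelector(mrmr_rank(train, k=k, **params))
    if name == "relieff":
        return _NameSelector(relieff_rank(train, k=k, **params))
    if name == "rfe":
        return _NameSelector(rfe_select(train, n_select=k, seed=seed, **params))
    if name == "importance":
        return _NameSelector(importance_rank(train, k=k, seed=seed, **params))
    raise ValueError(f"unknown selector {name!r}")


def benchmark_grid(
    table: FeatureTable,
    selectors: list[str] | None = None,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    k: int = 10,
    train_fraction: float = 0.8,
    selector_params: dict[str, dict] | None = None,
    leakage_safe: bool = True,
) -> list[MetricRow]:
    """Evaluate every selector x classifier combination on one holdout split.

    ``leakage_safe=True`` (default) fits each selector on the training
    partition only; the legacy alternative fits selectors on the full table
    before splitting, reproducing a common but optimistic pipeline layout.
    """
    if selectors is None:
        selectors = list(SELECTOR_KINDS)
    if specs is None:
        specs = default_classifier_specs(seed)
    if not selectors or not specs:
        raise ValueError("selectors and classifier specs must be non-empty")
    selector_params = selector_params or {}
    train, test = holdout_split(table, train_fraction=train_fraction, seed=seed)
    rows: list[MetricRow] = []
    for sel_name in selectors:
        fit_on = train if leakage_safe else table
        selector = fit_selector(
            sel_name, fit_on, k=k, seed=seed, params=selector_params.get(sel_name)
        )
        sel_train, sel_test = selector.apply(train), selector.apply(test)
        for spec in specs:
            row = train_eval(spec, sel_train, sel_test)
            row.selector = sel_name
            rows.append(row)
    return rows


def default_classifier_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The five benchmark classifiers at their study hyperparameters."""
    return [
        ClassifierSpec("lda", seed=seed),
        ClassifierSpec("svm_rbf", seed=seed),
        ClassifierSpec("rf", seed=seed),
        ClassifierSpec("mlp_hinge", seed=seed),
        ClassifierSpec("knn", seed=seed),
    ]


def grid_frame(rows: list[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "selector": r.selector,
            "classifier": r.classifier,
            "accuracy": r.accuracy,
            "recall": r.recall,
            "precision": r.precision,
            "f_measure": r.f_measure,
        }
        for r in rows
    ])


def write_report(rows: list[MetricRow], path, full_path=None) -> None:
    """Benchmark-table style report: percentages at 0 decimals, plus an
    optional full-precision companion file."""
    df = grid_frame(rows)
    rounded = df.copy()
    for col in ("accuracy", "recall", "precision", "f_measure"):
        rounded[col] = (100 * df[col]).round(0).astype(int)
    rounded.to_csv(path, index=False)
    if full_path is not None:
        df.to_csv(full_path, index=False)


# ---------------------------------------------------------------------------
# model / results interface

class PreferenceBenchmark:
    """Benchmark model over a labeled feature table.

    Parameters mirror :func:`benchmark_grid`; ``fit`` runs the grid and
    returns a :class:`BenchmarkResults`.

    Examples
    --------
    >>> bench = PreferenceBenchmark.from_dataframe(df)   # doctest: +SKIP
    >>> res = bench.fit(seed=7)                          # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(
        self,
        table: FeatureTable,
        selectors: list[str] | None = None,
        specs: list[ClassifierSpec] | None = None,
        k: int = 10,
        train_fraction: float = 0.8,
        selector_params: dict[str, dict] | None = None,
        leakage_safe: bool = True,
    ):
        self.table = table
        self.selectors = list(selectors) if selectors is not None else list(SELECTOR_KINDS)
        self.specs = specs
        self.k = k
        self.train_fraction = train_fraction
        self.selector_params = selector_params
        self.leakage_safe = leakage_safe

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PreferenceBenchmark":
        return cls(FeatureTable.from_dataframe(df), **kwargs)

    def fit(self, seed: int = 0) -> "BenchmarkResults":
        specs = self.specs or default_classifier_specs(seed)
        rows = benchmark_grid(
            self.table,
            selectors=self.selectors,
            specs=specs,
            seed=seed,
            k=self.k,
            train_fraction=self.train_fraction,
            selector_params=self.selector_params,
            leakage_safe=self.leakage_safe,
        )
        return BenchmarkResults(model=self, rows=rows, seed=seed)


@dataclass
class BenchmarkResults:
    """Fitted benchmark grid with a printable summary."""

    model: PreferenceBenchmark
    rows: list[MetricRow]
    seed: int

    @property
    def grid(self) -> pd.DataFrame:
        return grid_frame(self.rows)

    def best(self) -> MetricRow:
        return max(self.rows, key=lambda r: r.accuracy)

    def summary(self) -> str:
        df = self.grid.copy()
        for col in ("accuracy", "recall", "precision", "f_measure"):
            df[col] = (100 * df[col]).map("{:5.1f}".format)
        best = self.best()
        lines = [
            "Preference classification benchmark",
            f"  trials: {self.model.table.n_trials}   "
            f"features: {self.model.table.n_features}   "
            f"holdout: {self.model.train_fraction:.0%} train   seed: {self.seed}",
            f"  leakage-safe selector fitting: {self.model.leakage_safe}",
            "",
            df.to_string(index=False),
            "",
            f"  best: {best.classifier} with selector '{best.selector}' "
            f"at {100 * best.accuracy:.1f}% accuracy",
        ]
        return "\n".join(lines)

    def write(self, path, full_path=None) -> None:
        write_report(self.rows, path, full_path)
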