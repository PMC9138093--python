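import numpy as np
import pytest

from neuropref.selection import (
    FeatureTable,
    SelectionResult,
    importance_rank,
    mrmr_rank,
    mutual_info,
    pca_transform,
    relieff_rank,
    relieff_weights,
    rf_importance,
    rfe_select,
)


def table_from(X, y, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return FeatureTable(X, names, np.asarray(y))


# ---------------------------------------------------------------------------
# mutual information

class TestMutualInfo:
    def test_identical_balanced_binary_is_one_bit(self):
        y = np.repeat([0, 1], 50)
        assert mutual_info(y.astype(float), y) == pytest.approx(1.0)

    def test_independent_large_sample_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 2, 10_000)
        assert mutual_info(x, y) < 0.01

    def test_hand_computed_2x2_joint(self):
        """Joint counts [[40,10],[10,40]] -> plug-in MI by direct summation."""
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [40, 10, 10, 40])
        y = np.repeat([0, 1, 0, 1], [40, 10, 10, 40])
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert mutual_info(x, y) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert mutual_info(rng.standard_normal(60), rng.integers(0, 2, 60)) >= 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mutual_info(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            mutual_info(np.ones(10), np.ones(10), n_bins=1)


# ---------------------------------------------------------------------------
# mRMR

def brute_force_mrmr(table, k, scheme, n_bins=3):
    """Independent greedy evaluation of the relevance/redundancy criterion."""
    def binned(v):
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, v, side="right")

    def mi(a, b):
        va, vb = np.unique(a, return_inverse=True)[1], np.unique(b, return_inverse=True)[1]
        total = 0.0
        n = len(va)
        for i in np.unique(va):
            for j in np.unique(vb):
                pij = np.mean((va == i) & (vb == j))
                if pij > 0:
                    total += pij * np.log2(pij / (np.mean(va == i) * np.mean(vb == j)))
        return total

    cols = [binned(table.matrix[:, j]) for j in range(table.n_features)]
    rel = [mi(c, table.labels) for c in cols]
    chosen = []
    while len(chosen) < k:
        best, best_score = None, -np.inf
        for j in range(table.n_features):
            if j in chosen:
                continue
            if not chosen:
                score = rel[j]
            else:
                red = np.mean([mi(cols[j], cols[b]) for b in chosen])
                score = rel[j] - red if scheme == "MID" else rel[j] / max(red, 1e-12)
            if score > best_score:
                best, best_score = j, score
        chosen.append(best)
    return [table.feature_names[j] for j in chosen]


@pytest.fixture(scope="module")
def informative_table():
    rng = np.random.default_rng(11)
    n = 120
    y = np.repeat([0, 1], n // 2)
    f1 = y + rng.normal(0, 0.2, n)        # informative
    f2 = f1.copy()                         # exact copy of f1
    f3 = 0.3 * y + rng.normal(0, 1.0, n)   # weakly informative, independent
    return table_from(np.column_stack([f1, f2, f3]), y, ["f1", "f2", "f3"])


class TestMRMR:
    def test_first_pick_maximizes_relevance(self, informative_table):
        t = informative_table
        rel = [mutual_info(t.matrix[:, j], t.labels) for j in range(3)]
        for scheme in ("MID", "MIQ"):
            assert mrmr_rank(t, 1, scheme).selected[0] == t.feature_names[int(np.argmax(rel))]

    @pytest.mark.parametrize("scheme", ["MID", "MIQ"])
    def test_redundant_copy_deferred(self, informative_table, scheme):
        """The exact copy of the first pick is selected last."""
        assert mrmr_rank(informative_table, 3, scheme).selected == ["f1", "f3", "f2"]

    @pytest.mark.parametrize("scheme", ["MID", "MIQ"])
    def test_matches_brute_force_oracle(self, scheme):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, 60)
        X = rng.standard_normal((60, 5)) + 0.5 * y[:, None] * rng.standard_normal(5)
        t = table_from(X, y)
        result = mrmr_rank(t, 5, scheme)
        assert result.selected == brute_force_mrmr(t, 5, scheme)

    @pytest.mark.parametrize("scheme", ["MID", "MIQ"])
    def test_exhaustive_equivalence_on_six_features(self, scheme):
        rng = np.random.default_rng(31)
        y = rng.integers(0, 2, 80)
        X = rng.standard_normal((80, 6))
        X[:, 0] += y
        X[:, 3] += 0.5 * y
        t = table_from(X, y)
        assert mrmr_rank(t, 6, scheme).selected == brute_force_mrmr(t, 6, scheme)

    def test_k_clamped_with_warning(self, informative_table):
        with pytest.warns(UserWarning, match="clamp"):
            result = mrmr_rank(informative_table, 10)
        assert len(result.selected) == 3


# ---------------------------------------------------------------------------
# ReliefF

def brute_force_relieff(table, n_neighbors):
    """Direct evaluation of the hit/miss weight update formula."""
    X, y = table.matrix, table.labels
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / span
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    W = np.zeros(p)
    for i in range(n):
        d = np.abs(Z - Z[i]).sum(axis=1)
        d[i] = np.inf
        hits = sorted([j for j in range(n) if y[j] == y[i] and j != i], key=lambda j: d[j])
        for j in hits[:n_neighbors]:
            W -= np.abs(Z[j] - Z[i]) / (n * n_neighbors)
        for c in classes:
            if c == y[i]:
                continue
            misses = sorted([j for j in range(n) if y[j] == c], key=lambda j: d[j])
            coef = priors[c] / (1 - priors[y[i]])
            for j in misses[:n_neighbors]:
                W += coef * np.abs(Z[j] - Z[i]) / (n * n_neighbors)
    return W


class TestReliefF:
    def test_constant_feature_zero_weight(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 20)
        X = np.column_stack([np.full(40, 3.14), rng.standard_normal(40)])
        w = relieff_weights(table_from(X, y), n_neighbors=5)
        assert w[0] == 0.0

    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(8)
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 6))
        X[:, 3] = y * 2.0 + rng.normal(0, 0.05, n)  # near-perfect separator
        result = relieff_rank(table_from(X, y), k=6, n_neighbors=10)
        assert result.selected[0] == "f3"

    def test_matches_direct_formula_on_small_instance(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 10)
        X = rng.standard_normal((20, 4))
        X[:, 0] += y
        t = table_from(X, y)
        np.testing.assert_allclose(
            relieff_weights(t, n_neighbors=3), brute_force_relieff(t, 3), atol=1e-12
        )

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(19)
        y = np.repeat([0, 1], 25)
        X = rng.standard_normal((50, 3))
        t1 = table_from(X, y)
        X2 = X.copy()
        X2[:, 1] = 100.0 * X2[:, 1] - 7.0
        t2 = table_from(X2, y)
        np.testing.assert_allclose(
            relieff_weights(t1, 5), relieff_weights(t2, 5), atol=1e-12
        )

    def test_weights_bounded(self):
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 60)
        w = relieff_weights(table_from(rng.standard_normal((60, 5)), y), 10)
        assert np.all((-1 <= w) & (w <= 1))

    def test_small_class_rejected(self):
        y = np.array([0] * 3 + [1] * 30)
        with pytest.raises(ValueError, match="class"):
            relieff_weights(table_from(np.random.default_rng(0).standard_normal((33, 2)), y), 10)


# ---------------------------------------------------------------------------
# RF importance and RFE

class TestRFImportance:
    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        imp = rf_importance(table_from(rng.standard_normal((60, 8)), y), n_trees=50, seed=0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(imp >= 0)

    def test_informative_feature_dominates(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 21))
            X[:, 0] += 2.0 * y
            imp = rf_importance(table_from(X, y), n_trees=100, seed=seed)
            wins += int(np.argmax(imp) == 0)
        assert wins >= 8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 25)
        t = table_from(rng.standard_normal((50, 5)), y)
        np.testing.assert_array_equal(
            rf_importance(t, 50, seed=9), rf_importance(t, 50, seed=9)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            rf_importance(table_from(np.ones((10, 2)), np.zeros(10)))


class TestRFE:
    def test_identity_when_no_elimination(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 20)
        t = table_from(rng.standard_normal((40, 5)), y)
        result = rfe_select(t, n_select=5, n_trees=25)
        assert sorted(result.selected) == sorted(t.feature_names)

    def test_default_returns_ten_features(self):
        rng = np.random.default_rng(14)
        y = np.repeat([0, 1], 40)
        t = table_from(rng.standard_normal((80, 40)), y)
        result = rfe_select(t, n_trees=25)
        assert len(result.selected) == 10

    def test_informative_features_survive(self):
        survived = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 100
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 32))
            X[:, 0] += 2.0 * y
            X[:, 1] += 2.0 * y
            result = rfe_select(table_from(X, y), n_select=10, n_trees=50, seed=seed)
            survived += int({"f0", "f1"} <= set(result.selected))
        assert survived >= 9

    def test_invalid_n_select(self):
        t = table_from(np.random.default_rng(0).standard_normal((20, 4)),
                       np.repeat([0, 1], 10))
        with pytest.raises(ValueError):
            rfe_select(t, n_select=0)


# ---------------------------------------------------------------------------
# PCA

class TestPCA:
    def test_variance_ratios_sorted_and_bounded(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 25)
        _, ratios = pca_transform(table_from(rng.standard_normal((50, 6)), y), 4)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-9

    def test_rank_one_matrix(self):
        u = np.linspace(-1, 1, 30)
        X = np.outer(u, [1.0, 2.0, -0.5])
        y = (u > 0).astype(int)
        _, ratios = pca_transform(table_from(X, y), 2)
        assert ratios[0] >= 0.9999

    def test_matches_hand_eigendecomposition(self):
        """4x2 toy: components equal the closed-form 2x2 covariance eigenvectors."""
        X = np.array([[1.0, 2.0], [3.0, 3.0], [5.0, 7.0], [7.0, 8.0]])
        y = np.array([0, 0, 1, 1])
        centered = X - X.mean(axis=0)
        cov = centered.T @ centered / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        transformed, ratios = pca_transform(table_from(X, y), 2)
        np.testing.assert_allclose(ratios, evals / evals.sum(), atol=1e-12)
        for j in range(2):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(transformed.matrix[:, j], centered @ v, atol=1e-9)

    def test_invalid_components(self):
        t = table_from(np.random.default_rng(0).standard_normal((10, 3)),
                       np.repeat([0, 1], 5))
        with pytest.raises(ValueError):
            pca_transform(t, 0)
        with pytest.raises(ValueError):
            pca_transform(t, 5)


# ---------------------------------------------------------------------------
# cross-cutting contracts

def test_selection_result_invariants():
    with pytest.raises(ValueError, match="duplicate"):
        SelectionResult("m", ["a", "a"], [1.0, 2.0], 2)


def test_selectors_deterministic():
    rng = np.random.default_rng(55)
    y = np.repeat([0, 1], 30)
    t = table_from(rng.standard_normal((60, 12)), y)
    assert mrmr_rank(t, 5).selected == mrmr_rank(t, 5).selected
    assert relieff_rank(t, 5).selected == relieff_rank(t, 5, n_neighbors=10).selected
    assert rfe_select(t, 5, n_trees=25, seed=3).selected == \
        rfe_select(t, 5, n_trees=25, seed=3).selected


def test_importance_rank_orders_by_score():
    rng = np.random.default_rng(60)
    y = np.repeat([0, 1], 30)
    t = table_from(rng.standard_normal((60, 8)), y)
    result = importance_rank(t, 8, n_trees=50, seed=0)
    assert np.all(np.diff(result.scores) <= 0)
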