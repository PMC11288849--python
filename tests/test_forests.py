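"""Regression trees, random forest, quantile random forest."""

import numpy as np
import pytest

import selstack as ss
from selstack.forests import _split_kernel, _split_numpy, default_mtry


def test_best_split_toy_example():
    X = np.array([[0.0], [0.0], [1.0], [2.0]])
    y = np.array([1.0, 1.0, 5.0, 5.0])
    j, s, rss = ss.best_split(X, y)
    assert (j, s) == (0, 0.5)
    assert rss == pytest.approx(0.0, abs=1e-12)


def test_best_split_degenerate_cases():
    X = np.array([[0.0], [1.0]])
    assert ss.best_split(X, np.array([3.0, 3.0])) is None      # constant y
    X1 = np.array([[1.0], [1.0]])
    assert ss.best_split(X1, np.array([0.0, 1.0])) is None     # constant feature
    assert ss.best_split(np.array([[0.0]]), np.array([1.0])) is None  # 1 row


def test_best_split_tie_breaks_lowest_feature_then_smallest_s():
    # two identical informative features: the lower index must win
    X = np.column_stack([[0, 0, 1, 1], [0, 0, 1, 1]]).astype(float)
    y = np.array([0.0, 0.0, 4.0, 4.0])
    j, s, rss = ss.best_split(X, y)
    assert j == 0 and s == pytest.approx(0.5)


def test_split_kernel_matches_numpy_reference(rng):
    for _ in range(20):
        n = int(rng.integers(5, 40))
        k = int(rng.integers(1, 8))
        X = rng.integers(0, 3, size=(n, k)).astype(float)
        y = rng.standard_normal(n)
        a = _split_kernel(np.ascontiguousarray(X), np.ascontiguousarray(y))
        b = _split_numpy(X, y)
        assert a[0] == b[0]
        if a[0] >= 0:
            assert a[1] == pytest.approx(b[1])
            assert a[2] == pytest.approx(b[2], abs=1e-9)


def test_grow_tree_interpolates_with_min_node_one(rng):
    X = rng.standard_normal((30, 3))
    y = rng.standard_normal(30)
    tree = ss.grow_tree(X, y, min_node=1, rng=np.random.default_rng(0))
    np.testing.assert_allclose(tree.predict(X), y, atol=1e-12)


def test_grow_tree_single_leaf_when_min_node_is_n(rng):
    X = rng.standard_normal((20, 2))
    y = rng.standard_normal(20)
    tree = ss.grow_tree(X, y, min_node=20, rng=np.random.default_rng(0))
    assert tree.n_nodes == 1
    np.testing.assert_allclose(tree.predict(X), y.mean())


def test_grow_tree_deterministic(rng):
    X = rng.integers(0, 3, size=(40, 10)).astype(float)
    y = rng.standard_normal(40)
    t1 = ss.grow_tree(X, y, min_node=2, mtry=3, rng=np.random.default_rng(7))
    t2 = ss.grow_tree(X, y, min_node=2, mtry=3, rng=np.random.default_rng(7))
    np.testing.assert_array_equal(t1.feature, t2.feature)
    np.testing.assert_array_equal(t1.threshold, t2.threshold)


def test_grow_tree_validation(rng):
    with pytest.raises(ValueError, match="min_node"):
        ss.grow_tree(np.zeros((4, 1)), np.zeros(4), min_node=0)


def test_rf_defaults_match_convention():
    assert default_mtry(300) == 100
    f = ss.RandomForest()
    assert f.n_trees == 500 and f.min_node == 5
    with pytest.raises(ValueError, match="n_trees"):
        ss.RandomForest(n_trees=0)


def test_rf_single_tree_no_bootstrap_equals_tree(rng):
    X = rng.integers(0, 3, size=(50, 6)).astype(float)
    y = rng.standard_normal(50)
    f = ss.fit_rf(X, y, n_trees=1, seed=3, bootstrap=False, mtry=6)
    # the forest consumed identical rng draws as a directly grown tree
    tree = ss.grow_tree(X, y, min_node=5, mtry=6,
                        rng=np.random.default_rng(3), sample_idx=np.arange(50))
    np.testing.assert_allclose(f.predict(X), tree.predict(X), atol=1e-12)


def test_rf_conserves_constants(rng):
    X = rng.standard_normal((30, 4))
    y = np.full(30, 3.25)
    f = ss.fit_rf(X, y, n_trees=10, seed=0)
    np.testing.assert_allclose(f.predict(X), 3.25, atol=1e-12)


def test_rf_seed_reproducible(rng):
    X = rng.integers(0, 3, size=(60, 12)).astype(float)
    y = rng.standard_normal(60)
    p1 = ss.fit_rf(X, y, n_trees=25, seed=11).predict(X)
    p2 = ss.fit_rf(X, y, n_trees=25, seed=11).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_rf_prediction_within_response_range(rng):
    X = rng.standard_normal((80, 5))
    y = rng.standard_normal(80)
    f = ss.fit_rf(X, y, n_trees=30, seed=2)
    p = f.predict(rng.standard_normal((40, 5)))
    assert p.min() >= y.min() - 1e-12 and p.max() <= y.max() + 1e-12


def test_qrf_weights_two_observation_leaf():
    # single stump tree: x's leaf holds two observations with equal weight
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0.0, 1.0, 10.0, 11.0])
    f = ss.fit_qrf(X, y, n_trees=1, min_node=1, bootstrap=False, seed=0, mtry=1)
    w = ss.qrf_weights(f, np.array([0.0]))
    assert w[0] == pytest.approx(0.5) and w[1] == pytest.approx(0.5)
    assert w[2] == w[3] == 0.0


def test_qrf_weights_average_over_trees():
    # two single-leaf trees trained on disjoint bootstrap rows {0} and {1}
    X = np.array([[0.0], [1.0]])
    y = np.array([2.0, 4.0])
    f = ss.QuantileRandomForest(n_trees=2, min_node=1, seed=0)
    f.fit(X, y)
    # overwrite the bootstrap structure with the degenerate configuration
    f.trees = [ss.grow_tree(X, y, min_node=1, rng=np.random.default_rng(0),
                            sample_idx=np.array([i])) for i in (0, 1)]
    w = ss.qrf_weights(f, np.array([0.5]))
    np.testing.assert_allclose(w, [0.5, 0.5])


def test_qrf_weights_sum_to_one(rng):
    X = rng.integers(0, 3, size=(50, 8)).astype(float)
    y = rng.standard_normal(50)
    f = ss.fit_qrf(X, y, n_trees=20, seed=4)
    for _ in range(10):
        w = ss.qrf_weights(f, rng.integers(0, 3, size=8).astype(float))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_qrf_feature_mismatch_errors(rng):
    f = ss.fit_qrf(rng.standard_normal((20, 3)), rng.standard_normal(20),
                   n_trees=2, seed=0)
    with pytest.raises(ValueError, match="features"):
        ss.qrf_weights(f, np.zeros(5))


def test_predict_qrf_inf_rule():
    # weights (0.25, 0.25, 0.5) on y = (1, 2, 3)
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([1.0, 2.0, 3.0, 3.0])
    # single-leaf tree: every observation weighs 1/4, so F steps at 1, 2, 3
    f = ss.fit_qrf(X, y, n_trees=1, min_node=4, bootstrap=False, seed=0, mtry=1)
    w = ss.qrf_weights(f, np.array([0.5]))
    np.testing.assert_allclose(sorted(w), [0.25, 0.25, 0.25, 0.25])
    # F(1) = 0.25 < 0.5, F(2) = 0.5 -> Q(0.5) = 2 ; F(2) < 0.9 -> Q(0.9) = 3
    assert ss.predict_qrf(f, np.array([0.5]), 0.5) == pytest.approx(2.0)
    assert ss.predict_qrf(f, np.array([0.5]), 0.9) == pytest.approx(3.0)
    assert ss.predict_qrf(f, np.array([0.5]), 0.1) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="tau"):
        ss.predict_qrf(f, np.array([0.5]), 1.5)


def test_qrf_quantile_monotone_in_tau(rng):
    X = rng.integers(0, 3, size=(100, 10)).astype(float)
    y = X[:, 0] + rng.standard_normal(100)
    f = ss.fit_qrf(X, y, n_trees=30, seed=9)
    Xq = rng.integers(0, 3, size=(25, 10)).astype(float)
    Q = f.predict_quantiles(Xq, ss.QRF_TAUS)
    assert np.all(np.diff(Q, axis=1) >= -1e-12)


def test_qrf_interval_coverage(rng):
    # [Q0.1, Q0.9] should cover about 80% of held-out responses
    def make(n, r):
        X = r.uniform(-1, 1, size=(n, 5))
        y = 2 * X[:, 0] + X[:, 1] + r.standard_normal(n)
        return X, y

    Xtr, ytr = make(500, np.random.default_rng(42))
    Xte, yte = make(500, np.random.default_rng(43))
    f = ss.fit_qrf(Xtr, ytr, n_trees=100, seed=1)
    lo = f.predict_quantile(Xte, 0.1)
    hi = f.predict_quantile(Xte, 0.9)
    cover = float(np.mean((yte >= lo) & (yte <= hi)))
    assert cover == pytest.approx(0.80, abs=0.05)


def test_qrf_median_tracks_rf_mean_on_symmetric_noise(rng):
    # with symmetric noise the conditional median and mean agree, so the
    # tau=0.5 quantile forest and the mean forest should produce predictions
    # that differ by a small fraction of the response range (statistical)
    X = rng.integers(0, 3, size=(200, 6)).astype(float)
    y = X[:, 0] - X[:, 1] + rng.standard_normal(200)
    rf = ss.fit_rf(X, y, n_trees=60, seed=3)
    qf = ss.fit_qrf(X, y, n_trees=60, seed=3)
    Xq = rng.integers(0, 3, size=(50, 6)).astype(float)
    gap = np.abs(rf.predict(Xq) - qf.predict_quantile(Xq, 0.5))
    assert np.median(gap) < 0.25 * (y.max() - y.min())
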