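"""Regression trees, Random Forest, and Quantile Regression Forest.

Trees are grown by exhaustive recursive binary splitting: at each node every
candidate feature j and every midpoint s between consecutive distinct
observed values is scored by the summed residual sum of squares of the two
regions R1 = {X_j < s} and R2 = {X_j >= s}; the (j, s) pair with minimal RSS
wins, ties broken by lowest feature index then smallest s. Trees grow to
maximal size without pruning, stopping only when a node is smaller than
2 * min_node, its response is constant, or no split reduces the RSS.

The Random Forest averages leaf means over trees grown on bootstrap
resamples with ``mtry`` fresh candidate features per node (default
ceil(v/3), 500 trees). The Quantile Regression Forest keeps every leaf's
training observations (with bootstrap multiplicities): a query point x gets
weight 1/(leaf size * T) for each observation sharing its leaf per tree, the
weights define the conditional CDF F(y|x) = sum_i w_i 1{Y_i <= y}, and the
tau-quantile prediction is the smallest Y_i with F >= tau. The weights do
not depend on tau, so all nine quantile learners share one trained forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Tree",
    "RandomForest",
    "QuantileRandomForest",
    "best_split",
    "grow_tree",
    "fit_rf",
    "fit_qrf",
    "qrf_weights",
    "predict_qrf",
    "default_mtry",
]

_GAIN_EPS = 1e-12

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _split_kernel(Xs: np.ndarray, ys: np.ndarray):
    """Best (column, threshold, rss) over candidate columns; column -1 = none.

    Columns must be passed in ascending original-feature order so that the
    strict '<' comparison implements the lowest-j, then smallest-s tie-break.
    """
    n, k = Xs.shape
    total1 = 0.0
    total2 = 0.0
    for i in range(n):
        total1 += ys[i]
        total2 += ys[i] * ys[i]
    best_c = -1
    best_s = 0.0
    best_rss = np.inf
    for c in range(k):
        order = np.argsort(Xs[:, c])
        s1 = 0.0
        s2 = 0.0
        for i in range(n - 1):
            yi = ys[order[i]]
            s1 += yi
            s2 += yi * yi
            xa = Xs[order[i], c]
            xb = Xs[order[i + 1], c]
            if xa == xb:
                continue
            nl = i + 1
            nr = n - nl
            rl = s2 - s1 * s1 / nl
            rr = (total2 - s2) - (total1 - s1) * (total1 - s1) / nr
            rss = rl + rr
            if rss < best_rss:
                best_rss = rss
                best_c = c
                best_s = 0.5 * (xa + xb)
    return best_c, best_s, best_rss


def _split_numpy(Xs: np.ndarray, ys: np.ndarray):
    """Pure-numpy reference implementation of ``_split_kernel``."""
    n, k = Xs.shape
    total1, total2 = ys.sum(), (ys ** 2).sum()
    best = (-1, 0.0, np.inf)
    for c in range(k):
        order = np.argsort(Xs[:, c], kind="stable")
        xs, yo = Xs[order, c], ys[order]
        s1, s2 = np.cumsum(yo)[:-1], np.cumsum(yo ** 2)[:-1]
        nl = np.arange(1, n)
        nr = n - nl
        valid = xs[:-1] != xs[1:]
        if not valid.any():
            continue
        rss = (s2 - s1 ** 2 / nl) + ((total2 - s2) - (total1 - s1) ** 2 / nr)
        rss = np.where(valid, rss, np.inf)
        i = int(np.argmin(rss))
        if rss[i] < best[2]:
            best = (c, 0.5 * (xs[i] + xs[i + 1]), float(rss[i]))
    return best


@dataclass
class Tree:
    """Flat-array regression tree.

    Internal nodes carry (feature, threshold); leaves carry the list of
    training observation indices that fell into them (bootstrap
    multiplicities included) and the corresponding response mean.
    """

    feature: np.ndarray    # int, -1 for leaf
    threshold: np.ndarray  # float
    left: np.ndarray       # int child index
    right: np.ndarray
    value: np.ndarray      # leaf response mean
    leaf_obs: list         # per-node array of training indices (leaves only)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaf_of(self, x: np.ndarray) -> int:
        i = 0
        while self.feature[i] >= 0:
            i = self.left[i] if x[self.feature[i]] < self.threshold[i] else self.right[i]
        return int(i)

    def leaf_indices(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index per row of X (vectorized routing)."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            f = self.feature[node[idx]]
            t = self.threshold[node[idx]]
            go_left = X[idx, f] < t
            node[idx] = np.where(go_left, self.left[node[idx]], self.right[node[idx]])
            active = self.feature[node] >= 0
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.leaf_indices(np.asarray(X, dtype=float))]


def best_split(
    X_node: np.ndarray,
    y_node: np.ndarray,
    candidate_features: Optional[Sequence[int]] = None,
):
    """Exhaustive best split; returns (j, s, rss) or None when unsplittable.

    j is the original feature index, s the midpoint threshold, rss the summed
    two-region residual sum of squares. Returns None when every candidate
    feature is constant, the response is constant, or fewer than 2 rows.
    """
    X_node = np.asarray(X_node, dtype=float)
    if X_node.ndim == 1:
        X_node = X_node[:, None]
    y_node = np.asarray(y_node, dtype=float)
    if X_node.shape[0] < 2 or np.all(y_node == y_node[0]):
        return None
    if candidate_features is None:
        feats = np.arange(X_node.shape[1])
    else:
        feats = np.sort(np.asarray(candidate_features, dtype=int))
    Xs = np.ascontiguousarray(X_node[:, feats])
    kernel = _split_kernel if _HAVE_NUMBA else _split_numpy
    c, s, rss = kernel(Xs, np.ascontiguousarray(y_node))
    if c < 0:
        return None
    mean = y_node.mean()
    node_rss = float(((y_node - mean) ** 2).sum())
    if not rss < node_rss - _GAIN_EPS * max(1.0, node_rss):
        return None
    return int(feats[c]), float(s), float(max(rss, 0.0))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_node: int = 5,
    mtry: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sample_idx: Optional[np.ndarray] = None,
) -> Tree:
    """Grow one unpruned regression tree.

    ``mtry`` candidate features are freshly drawn at every node; ``sample_idx``
    selects the (bootstrap) training rows, with multiplicity.
    """
    if min_node < 1:
        raise ValueError("min_node must be >= 1")
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    n, v = X.shape
    mtry = v if mtry is None else min(max(int(mtry), 1), v)
    rng = rng or np.random.default_rng()
    idx0 = np.arange(n) if sample_idx is None else np.asarray(sample_idx, dtype=np.int64)

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    leaf_obs: list = []

    def make_leaf(idx: np.ndarray) -> int:
        node = len(feature)
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(float(y[idx].mean()))
        leaf_obs.append(idx.copy())
        return node

    def build(idx: np.ndarray) -> int:
        yn = y[idx]
        if len(idx) < 2 * min_node or np.all(yn == yn[0]):
            return make_leaf(idx)
        feats = np.sort(rng.choice(v, size=mtry, replace=False))
        found = best_split(X[idx], yn, candidate_features=feats)
        if found is None:
            return make_leaf(idx)
        j, s, _ = found
        mask = X[idx, j] < s
        if not mask.any() or mask.all():
            # the midpoint rounded onto an endpoint (adjacent floats); the
            # split would create an empty child, so close the node instead
            return make_leaf(idx)
        node = len(feature)
        feature.append(j)
        threshold.append(s)
        left.append(-1)
        right.append(-1)
        value.append(float(yn.mean()))
        leaf_obs.append(None)
        li = build(idx[mask])
        ri = build(idx[~mask])
        left[node] = li
        right[node] = ri
        return node

    build(idx0)
    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        value=np.asarray(value, dtype=float),
        leaf_obs=leaf_obs,
    )


def default_mtry(v: int) -> int:
    """Candidate features per node: ceiling of v / 3."""
    return int(np.ceil(v / 3.0))


class _Forest:
    """Shared machinery of RandomForest and QuantileRandomForest."""

    mode = "mean"

    def __init__(self, n_trees: int = 500, mtry: Optional[int] = None,
                 min_node: int = 5, bootstrap: bool = True,
                 seed: Optional[int] = None):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if min_node < 1:
            raise ValueError("min_node must be >= 1")
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.min_node = int(min_node)
        self.bootstrap = bootstrap
        self.seed = seed
        self.trees: list[Tree] = []
        self.sample_indices: list[np.ndarray] = []
        self.y_train: Optional[np.ndarray] = None
        self.n_features_: Optional[int] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        X = np.ascontiguousarray(X, dtype=float)
        y = np.ascontiguousarray(y, dtype=float)
        n, v = X.shape
        if v < 1:
            raise ValueError("need at least one feature")
        mtry = default_mtry(v) if self.mtry is None else min(int(self.mtry), v)
        self.mtry_ = mtry
        rng = np.random.default_rng(self.seed)
        self.trees = []
        self.sample_indices = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            tree = grow_tree(X, y, min_node=self.min_node, mtry=mtry,
                             rng=rng, sample_idx=idx)
            self.trees.append(tree)
            self.sample_indices.append(idx)
        self.y_train = y
        self.n_features_ = v
        return self

    def _check_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"query has {X.shape[1]} features, model trained with {self.n_features_}"
            )
        return np.ascontiguousarray(X)


class RandomForest(_Forest):
    """Bootstrap-aggregated regression trees; prediction = mean of leaf means."""

    mode = "mean"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check_features(X)
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += tree.predict(X)
        return out / len(self.trees)


class QuantileRandomForest(_Forest):
    """Forest retaining leaf response distributions for quantile prediction."""

    mode = "distribution"

    def weights_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_query, n_train) observation weights; each row sums to 1.

        Per tree, every training observation in a query's leaf contributes
        1/(leaf size * T), counting bootstrap multiplicities.
        """
        X = self._check_features(X)
        n_train = len(self.y_train)
        T = len(self.trees)
        W = np.zeros((X.shape[0], n_train))
        for tree in self.trees:
            leaves = tree.leaf_indices(X)
            for leaf in np.unique(leaves):
                rows = np.flatnonzero(leaves == leaf)
                obs = tree.leaf_obs[leaf]
                np.add.at(W, (rows[:, None], obs[None, :]), 1.0 / (len(obs) * T))
        return W

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-training-observation weights for one query row."""
        x = self._check_features(x)
        if x.shape[0] != 1:
            raise ValueError("weights() takes a single query row")
        return self.weights_matrix(x)[0]

    def predict_quantiles(self, X: np.ndarray, taus: Sequence[float]) -> np.ndarray:
        """Q_tau(x) = inf {y : F(y|x) >= tau}; returns (n_query, len(taus))."""
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if ((taus <= 0.0) | (taus >= 1.0)).any():
            raise ValueError("tau must lie strictly between 0 and 1")
        X = self._check_features(X)
        order = np.argsort(self.y_train, kind="stable")
        y_sorted = self.y_train[order]
        cdf = np.cumsum(self.weights_matrix(X)[:, order], axis=1)
        out = np.empty((X.shape[0], len(taus)))
        for k, tau in enumerate(taus):
            idx = np.argmax(cdf >= tau - 1e-12, axis=1)
            # rows whose cdf never reaches tau (numerical fringe) take max(y)
            never = cdf[:, -1] < tau - 1e-12
            idx[never] = len(y_sorted) - 1
            out[:, k] = y_sorted[idx]
        return out

    def predict_quantile(self, X: np.ndarray, tau: float) -> np.ndarray:
        return self.predict_quantiles(X, [float(tau)])[:, 0]

    def predict(self, X: np.ndarray, tau: float = 0.5) -> np.ndarray:
        return self.predict_quantile(X, tau)


def fit_rf(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
           mtry: Optional[int] = None, min_node: int = 5,
           seed: Optional[int] = None, bootstrap: bool = True) -> RandomForest:
    """Fit a Random Forest (functional wrapper)."""
    return RandomForest(n_trees=n_trees, mtry=mtry, min_node=min_node,
                        bootstrap=bootstrap, seed=seed).fit(X, y)


def fit_qrf(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
            mtry: Optional[int] = None, min_node: int = 5,
            seed: Optional[int] = None, bootstrap: bool = True) -> QuantileRandomForest:
    """Fit a Quantile Regression Forest (functional wrapper)."""
    return QuantileRandomForest(n_trees=n_trees, mtry=mtry, min_node=min_node,
                                bootstrap=bootstrap, seed=seed).fit(X, y)


def qrf_weights(model: QuantileRandomForest, x: np.ndarray) -> np.ndarray:
    if model.mode != "distribution":
        raise ValueError("weights require a distribution-mode forest")
    return model.weights(x)


def predict_qrf(model: QuantileRandomForest, x: np.ndarray, tau: float):
    out = model.predict_quantile(x, tau)
    return float(out[0]) if np.asarray(x).ndim == 1 else out
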