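"""Gradient-boosted regression trees, written from first principles.

Squared-error boosting: the initial learner f0 is the target mean (the
argmin of the summed loss over constants); each round fits a depth-bounded
CART regression tree to the pseudo-residuals y - f_{m-1}(x) by greedy
variance-reduction splits, sets each leaf value to the mean residual in its
region, and updates f_m = f_{m-1} + shrinkage * tree_m(x). The leaf regions
of every tree partition feature space, so prediction is f0 plus the
shrunken sum of matched-leaf values.

This learner exists on its own (rather than wrapping a library) because the
imputation method it supports is itself under test down to the split rule;
an independent library implementation serves as a cross-check in the test
suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import ConfigError, SchemaError

__all__ = ["TreeNode", "RegressionTree", "GbrtModel", "gbrt_fit", "gbrt_predict"]


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (value)."""

    value: float = 0.0
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exact greedy search for the SSE-minimizing axis-aligned split.

    Returns (feature, threshold, gain) or None when no split satisfying the
    leaf-size constraint reduces the SSE. Thresholds are midpoints between
    adjacent distinct sorted values; ties break towards the lowest feature
    index then the lowest threshold, so fits are order-deterministic.
    """
    n, d = X.shape
    if n < 2 * min_leaf:
        return None
    total_sum = y.sum()
    total_sq = (y * y).sum()
    sse_parent = total_sq - total_sum**2 / n
    best = None
    best_gain = 1e-12  # require a strictly positive SSE reduction
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys * ys)
        # candidate split after position i (1-based left size i+1)
        sizes = np.arange(1, n)
        valid = (sizes >= min_leaf) & (n - sizes >= min_leaf) & (xs[:-1] < xs[1:])
        if not valid.any():
            continue
        idx = np.nonzero(valid)[0]
        nl = idx + 1
        nr = n - nl
        sl, ql = csum[idx], csq[idx]
        sr, qr = total_sum - sl, total_sq - ql
        sse = (ql - sl**2 / nl) + (qr - sr**2 / nr)
        gains = sse_parent - sse
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            thr = float((xs[idx[k]] + xs[idx[k] + 1]) / 2.0)
            best = (j, thr, best_gain)
    return best


def _grow(X, y, depth, max_depth, min_leaf) -> TreeNode:
    node = TreeNode(value=float(y.mean()))
    if depth >= max_depth:
        return node
    split = _best_split(X, y, min_leaf)
    if split is None:
        return node
    j, thr, _ = split
    go_left = X[:, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow(X[go_left], y[go_left], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~go_left], y[~go_left], depth + 1, max_depth, min_leaf)
    return node


@dataclass
class RegressionTree:
    """Depth-bounded CART regression tree (squared-error criterion)."""

    root: TreeNode
    max_depth: int
    min_leaf: int

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, max_depth: int, min_leaf: int):
        return cls(_grow(X, y, 0, max_depth, min_leaf), max_depth, min_leaf)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf or len(idx) == 0:
                out[idx] = node.value
                continue
            left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[left]))
            stack.append((node.right, idx[~left]))
        return out

    def n_leaves(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                count += 1
            else:
                stack.extend([node.left, node.right])
        return count


@dataclass
class GbrtModel:
    """Fitted boosted ensemble: f(x) = f0 + shrinkage * sum_m tree_m(x)."""

    f0: float
    shrinkage: float
    trees: list[RegressionTree] = field(default_factory=list)
    feature_names: list[str] | None = None
    n_features: int | None = None
    loss: str = "squared_error"

    @property
    def rounds(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return gbrt_predict(self, X)

    def staged_predict(self, X: np.ndarray):
        """Yield predictions after each boosting round (for loss curves)."""
        X = _check_features(self, X)
        pred = np.full(len(X), self.f0)
        for tree in self.trees:
            pred = pred + self.shrinkage * tree.predict(X)
            yield pred.copy()


def _check_features(model: GbrtModel, X) -> np.ndarray:
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        if model.feature_names is not None:
            missing = [c for c in model.feature_names if c not in X.columns]
            if missing:
                raise SchemaError(f"missing feature columns: {missing}")
            X = X[model.feature_names]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SchemaError("feature matrix must be 2-D")
    expected = model.n_features if model.n_features is not None else (
        len(model.feature_names) if model.feature_names is not None else None
    )
    if expected is not None and X.shape[1] != expected:
        raise SchemaError(f"expected {expected} feature columns, got {X.shape[1]}")
    if np.isnan(X).any():
        raise ConfigError("feature matrix contains missing values")
    return X


def gbrt_fit(
    features,
    target,
    rounds: int = 100,
    shrinkage: float = 0.1,
    max_depth: int = 3,
    min_leaf: int = 5,
    feature_names: list[str] | None = None,
) -> GbrtModel:
    """Fit the boosted ensemble on complete numeric data.

    ``rounds`` (M) trees of depth <= ``max_depth`` with >= ``min_leaf``
    samples per leaf; ``shrinkage`` in (0, 1] scales every tree's
    contribution. A constant target yields the f0-only model (every tree
    degenerates to a zero-valued root).
    """
    import pandas as pd

    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        features = features.to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ConfigError("features must be 2-D and aligned with target")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ConfigError("gbrt_fit requires complete (non-missing) inputs")
    if rounds < 1:
        raise ConfigError("rounds must be >= 1")
    if not (0.0 < shrinkage <= 1.0):
        raise ConfigError("shrinkage must lie in (0, 1]")
    if len(y) < 2 * min_leaf:
        raise ConfigError(f"need n >= 2*min_leaf = {2 * min_leaf}, got n = {len(y)}")

    model = GbrtModel(f0=float(y.mean()), shrinkage=shrinkage,
                      feature_names=feature_names, n_features=X.shape[1])
    pred = np.full(len(y), model.f0)
    for _ in range(rounds):
        residual = y - pred
        tree = RegressionTree.fit(X, residual, max_depth=max_depth, min_leaf=min_leaf)
        model.trees.append(tree)
        pred = pred + shrinkage * tree.predict(X)
    return model


def gbrt_predict(model: GbrtModel, features) -> np.ndarray:
    """Evaluate f0 + shrinkage * sum of matched-leaf values; deterministic."""
    X = _check_features(model, features)
    pred = np.full(len(X), model.f0)
    for tree in model.trees:
        pred = pred + model.shrinkage * tree.predict(X)
    return pred
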