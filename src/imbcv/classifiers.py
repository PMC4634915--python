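"""Classifier contract: CART as the workhorse, 1-NN for leakage illustrations.

The CART configuration follows the classic recursive-partitioning defaults:
Gini impurity for split selection, splits attempted whenever a node holds at
least two samples, depth up to 30, and cost-complexity pruning with
complexity parameter ``cp = 0.01``.  Pruning uses the standard weakest-link
rule on the *misclassification* risk scale: the reported tree is the subtree
minimizing ``R(T) + cp * R(root) * |leaves(T)|``, so a split survives only if
it reduces the training misclassification risk by at least ``cp * R(root)``.
Setting ``cart_pruning=0`` keeps the fully grown tree, which interpolates its
training data (zero training error whenever no feature vector appears in both
classes) — the capacity that converts train/test replica leakage into
inflated cross-validated scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .datasets import Dataset

__all__ = ["ClassifierSpec", "FittedModel", "fit", "predict_scores", "predict_classes"]


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "cart"  # cart | knn
    cart_min_split: int = 2
    cart_max_depth: int = 30
    cart_pruning: float = 0.01  # cost-complexity cp on the risk scale; 0 = fully grown tree
    knn_neighbors: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("cart", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.cart_min_split < 2:
            raise ValueError("cart_min_split must be >= 2")
        if self.cart_max_depth < 1:
            raise ValueError("cart_max_depth must be >= 1")
        if not 0.0 <= self.cart_pruning <= 1.0:
            raise ValueError("cart_pruning must be in [0, 1]")
        if self.knn_neighbors < 1:
            raise ValueError("knn_neighbors must be >= 1")


@dataclass
class FittedModel:
    """Opaque fitted model.

    For CART, ``terminal`` maps every node of the grown tree to its effective
    terminal node after pruning, and ``node_score`` holds each node's minority
    class proportion; for k-NN both are None.
    """

    estimator: object
    minority_col: int
    n_features: int
    terminal: np.ndarray | None = None
    node_score: np.ndarray | None = None


def _node_class_counts(tree) -> np.ndarray:
    """Per-node class counts, robust to sklearn's value normalization."""
    value = tree.value[:, 0, :].copy()
    wn = tree.weighted_n_node_samples
    # Recent sklearn stores per-node class *fractions*; rescale to counts.
    if np.allclose(value.sum(axis=1), 1.0):
        value = value * wn[:, None]
    return value


def _prune_cp(tree, cp: float) -> np.ndarray:
    """Weakest-link pruning on misclassification risk.

    Returns ``terminal``: for each node, the node that acts as its leaf after
    pruning (itself, or the nearest collapsed ancestor).  The selected subtree
    minimizes ``R(T) + alpha * |leaves(T)|`` with ``alpha = cp * R(root)``;
    ties collapse, preferring the smaller tree.
    """
    n_nodes = tree.node_count
    left, right = tree.children_left, tree.children_right
    counts = _node_class_counts(tree)
    risk = tree.weighted_n_node_samples - counts.max(axis=1)  # misclassified count
    alpha = cp * risk[0]

    cost = np.empty(n_nodes)
    collapse = np.zeros(n_nodes, dtype=bool)
    # children always have larger indices than their parent, so a reverse
    # sweep is a bottom-up traversal
    for i in range(n_nodes - 1, -1, -1):
        leaf_cost = risk[i] + alpha
        if left[i] == -1:
            cost[i] = leaf_cost
            collapse[i] = True
        else:
            sub = cost[left[i]] + cost[right[i]]
            if leaf_cost <= sub + 1e-9:
                cost[i] = leaf_cost
                collapse[i] = True
            else:
                cost[i] = sub

    terminal = np.empty(n_nodes, dtype=np.intp)
    stack = [(0, -1)]
    while stack:
        i, eff = stack.pop()
        if eff == -1 and collapse[i]:
            eff = i
        terminal[i] = eff if eff != -1 else i
        if left[i] != -1:
            stack.append((left[i], eff))
            stack.append((right[i], eff))
    return terminal


def fit(spec: ClassifierSpec, train: Dataset) -> FittedModel:
    """Fit the specified classifier; errors on a single-class training set
    (which signals a degenerate fold upstream).  Deterministic given inputs."""
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError(
            "training set contains a single class; cannot fit a classifier "
            "(degenerate fold?)"
        )
    if spec.kind == "cart":
        est = DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=spec.cart_min_split,
            max_depth=spec.cart_max_depth,
            random_state=0,
        )
        est.fit(train.features, train.labels)
        minority_col = int(np.flatnonzero(est.classes_ == 1)[0])
        if spec.cart_pruning > 0:
            terminal = _prune_cp(est.tree_, spec.cart_pruning)
        else:
            terminal = np.arange(est.tree_.node_count, dtype=np.intp)
        counts = _node_class_counts(est.tree_)
        node_score = counts[:, minority_col] / est.tree_.weighted_n_node_samples
        return FittedModel(est, minority_col, train.features.shape[1], terminal, node_score)

    est = KNeighborsClassifier(n_neighbors=spec.knn_neighbors)
    est.fit(train.features, train.labels)
    minority_col = int(np.flatnonzero(est.classes_ == 1)[0])
    return FittedModel(est, minority_col, train.features.shape[1])


def predict_scores(model: FittedModel, test_features: np.ndarray) -> np.ndarray:
    """Minority-class score in [0, 1] per test row.

    For CART this is the minority proportion in the (pruned) leaf the row
    falls into; for k-NN the fraction of minority samples among the k
    neighbours.
    """
    test_features = np.asarray(test_features, dtype=float)
    if test_features.ndim != 2 or test_features.shape[1] != model.n_features:
        raise ValueError(
            f"expected a 2-D matrix with {model.n_features} columns, "
            f"got shape {test_features.shape}"
        )
    if model.terminal is not None:
        leaves = model.estimator.apply(test_features)
        return model.node_score[model.terminal[leaves]]
    return model.estimator.predict_proba(test_features)[:, model.minority_col]


def predict_classes(
    model: FittedModel, test_features: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Class = minority iff score strictly exceeds the threshold.

    A score exactly at the threshold goes to the majority class — conservative
    with respect to minority-accuracy claims, and it makes PA_min well defined
    when a tree leaf is perfectly mixed.
    """
    return (predict_scores(model, test_features) > threshold).astype(int)
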