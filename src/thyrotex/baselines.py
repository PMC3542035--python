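"""Comparison methods: mean-brightness thresholding and a pruned decision tree.

Method 1 classifies an ROI as diseased when its mean brightness, as a
fraction of saturation (255), falls strictly below a threshold — inflamed
tissue is hypoechogenic (darker).  The sweep covers thresholds 13 %..36 %
in increments of 2.9 % and reports resubstitution accuracy (no split).

Method 2 grows a binary CART on (w1, w2, w3) with Gini impurity, builds
the cost-complexity (weakest-link) pruning sequence, and selects the
prune level by the 1-SE rule on 10-fold cross-validation over the
training partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .discriminant_suite import LabeledSample, _CLASS_ORDER
from .synthetic_cohort import HEALTHY, PATIENT

__all__ = [
    "ThresholdModel",
    "TreeNode",
    "TreeModel",
    "method1_classify",
    "method1_threshold_sweep",
    "default_sweep_thresholds",
    "method2_fit",
    "method2_predict",
]

FEATURE_NAMES = ("w1", "w2", "w3")
MIN_SPLIT_SAMPLES = 5
MAX_PRUNE_LEVEL = 6


@dataclass(frozen=True)
class ThresholdModel:
    """Method 1: mean-brightness threshold as a fraction of saturation."""

    threshold_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError(
                f"threshold_fraction must lie in (0, 1) (got {self.threshold_fraction})"
            )
        if not 0.13 <= self.threshold_fraction <= 0.362:
            warnings.warn(
                f"threshold {self.threshold_fraction} is outside the standard "
                "sweep range [0.13, 0.36]",
                stacklevel=3,
            )


@dataclass
class TreeNode:
    """One node of a binary classification tree; ``<=`` goes left."""

    prediction: str
    n_samples: int
    n_errors: int  # training misclassifications if this node were a leaf
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"prediction": self.prediction, "n_samples": self.n_samples}
        if not self.is_leaf:
            d["feature"] = FEATURE_NAMES[self.feature]
            d["threshold"] = self.threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class TreeModel:
    """Method 2: CART with a selected cost-complexity prune level."""

    root: TreeNode
    prune_level: int
    pruned_roots: list[TreeNode] = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {"prune_level": self.prune_level, "tree": self.active_root().to_dict()},
            indent=2,
        )

    def active_root(self) -> TreeNode:
        return self.pruned_roots[self.prune_level] if self.pruned_roots else self.root


def method1_classify(ls: np.ndarray, model: ThresholdModel) -> str:
    """Label an ROI: patient iff mean(ls)/255 strictly below the threshold."""
    mean_fraction = float(np.asarray(ls, dtype=float).mean()) / 255.0
    return PATIENT if mean_fraction < model.threshold_fraction else HEALTHY


def default_sweep_thresholds() -> list[float]:
    """The nine sweep thresholds 0.13, 0.159, ..., 0.362 (step 0.029)."""
    return [round(0.13 + 0.029 * k, 3) for k in range(9)]


def method1_threshold_sweep(
    rois: list[tuple[np.ndarray, str]], thresholds: Optional[list[float]] = None
) -> pd.DataFrame:
    """Resubstitution confusion counts and ACC per threshold over the full cohort.

    ``rois`` holds (ROI image, true label) pairs.
    """
    if not rois:
        raise ValueError("cannot sweep an empty cohort")
    if thresholds is None:
        thresholds = default_sweep_thresholds()
    rows = []
    for t in thresholds:
        model = ThresholdModel(threshold_fraction=t)
        tp = tn = fp = fn = 0
        for ls, label in rois:
            pred = method1_classify(ls, model)
            if label == PATIENT:
                tp += pred == PATIENT
                fn += pred == HEALTHY
            else:
                tn += pred == HEALTHY
                fp += pred == PATIENT
        total = tp + tn + fp + fn
        rows.append(
            {"threshold": t, "TP": tp, "TN": tn, "FP": fp, "FN": fn, "ACC": (tp + tn) / total}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Method 2: CART with cost-complexity pruning and 1-SE selection
# ---------------------------------------------------------------------------


def _majority(y: np.ndarray) -> tuple[str, int]:
    # ties toward healthy: _CLASS_ORDER lists healthy first and ">" is strict
    best, best_count = None, -1
    for label in _CLASS_ORDER:
        count = int(np.sum(y == label))
        if count > best_count:
            best, best_count = label, count
    return best, len(y) - best_count


def _gini(y: np.ndarray) -> float:
    n = len(y)
    if n == 0:
        return 0.0
    g = 1.0
    for label in _CLASS_ORDER:
        p = np.sum(y == label) / n
        g -= p * p
    return g


def _best_split(X: np.ndarray, y: np.ndarray) -> Optional[tuple[int, float, float]]:
    """Exhaustive single-feature threshold search minimizing weighted Gini."""
    n = len(y)
    best = None
    parent = _gini(y)
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        if len(values) < 2:
            continue
        cuts = (values[:-1] + values[1:]) / 2.0
        for t in cuts:
            mask = X[:, j] <= t
            nl = int(mask.sum())
            if nl == 0 or nl == n:
                continue
            score = (nl * _gini(y[mask]) + (n - nl) * _gini(y[~mask])) / n
            if best is None or score < best[2] - 1e-15:
                best = (j, float(t), score)
    if best is None or best[2] >= parent - 1e-15:
        return None
    return best


def _grow(X: np.ndarray, y: np.ndarray) -> TreeNode:
    pred, errors = _majority(y)
    node = TreeNode(prediction=pred, n_samples=len(y), n_errors=errors)
    if len(y) < MIN_SPLIT_SAMPLES or errors == 0:
        return node
    split = _best_split(X, y)
    if split is None:
        return node
    j, t, _ = split
    mask = X[:, j] <= t
    node.feature, node.threshold = j, t
    node.left = _grow(X[mask], y[mask])
    node.right = _grow(X[~mask], y[~mask])
    return node


def _copy_tree(node: TreeNode) -> TreeNode:
    out = TreeNode(
        prediction=node.prediction,
        n_samples=node.n_samples,
        n_errors=node.n_errors,
        feature=node.feature,
        threshold=node.threshold,
    )
    if not node.is_leaf:
        out.left = _copy_tree(node.left)
        out.right = _copy_tree(node.right)
    return out


def _subtree_stats(node: TreeNode) -> tuple[int, int]:
    """(training errors of the subtree, number of leaves)."""
    if node.is_leaf:
        return node.n_errors, 1
    el, ll = _subtree_stats(node.left)
    er, lr = _subtree_stats(node.right)
    return el + er, ll + lr


def _weakest_alpha(node: TreeNode) -> tuple[float, TreeNode]:
    """Smallest g(t) = (R(leaf) - R(subtree)) / (leaves - 1) over internal nodes."""
    best_alpha, best_node = np.inf, None
    stack = [node]
    while stack:
        t = stack.pop()
        if t.is_leaf:
            continue
        err_sub, leaves = _subtree_stats(t)
        g = (t.n_errors - err_sub) / (leaves - 1)
        if best_node is None or g < best_alpha:
            best_alpha, best_node = g, t
        stack.extend([t.left, t.right])
    return best_alpha, best_node


def _pruning_sequence(root: TreeNode) -> tuple[list[TreeNode], list[float]]:
    """Trees for prune levels 0..L and the alpha at which each prune occurred."""
    roots = [root]
    alphas = [0.0]
    current = root
    while not current.is_leaf and len(roots) <= MAX_PRUNE_LEVEL:
        current = _copy_tree(current)
        alpha, node = _weakest_alpha(current)
        node.feature = node.threshold = node.left = node.right = None
        roots.append(current)
        alphas.append(float(alpha))
    return roots, alphas


def _predict_node(node: TreeNode, x: np.ndarray) -> str:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.prediction


def _prune_with_alpha(root: TreeNode, alpha: float) -> TreeNode:
    current = root
    while not current.is_leaf:
        a, node = _weakest_alpha(current)
        if a > alpha + 1e-12:
            break
        current = _copy_tree(current)
        _, node = _weakest_alpha(current)
        node.feature = node.threshold = node.left = node.right = None
    return current


def method2_fit(
    train: list[LabeledSample],
    validation: Optional[list[LabeledSample]] = None,
    seed: int = 0,
) -> TreeModel:
    """Grow the CART and select the prune level by the 1-SE rule.

    Ten-fold cross-validation on the training samples estimates the error
    of each pruning alpha; the selected tree is the smallest one whose CV
    error does not exceed the minimum by more than one standard error.
    The validation partition, when given, is folded into the CV pool.
    """
    pool = list(train) + list(validation or [])
    X = np.array([s.features.as_array() for s in pool], dtype=float)
    y = np.array([s.label for s in pool])
    if len(set(y)) < 2:
        raise ValueError("method 2 requires both classes in the training data")

    root = _grow(X, y)
    roots, alphas = _pruning_sequence(root)

    # CV error per candidate alpha (geometric midpoints, CART convention).
    candidates = []
    for i, a in enumerate(alphas):
        nxt = alphas[i + 1] if i + 1 < len(alphas) else np.inf
        candidates.append(np.sqrt(a * nxt) if np.isfinite(nxt) and a > 0 else a)

    n = len(y)
    n_folds = min(10, n)
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(fold_of)

    cv_err = np.zeros(len(candidates))
    cv_sq = np.zeros(len(candidates))
    for f in range(n_folds):
        hold = fold_of == f
        sub_root = _grow(X[~hold], y[~hold])
        for ci, alpha in enumerate(candidates):
            pruned = _prune_with_alpha(sub_root, alpha)
            miss = sum(_predict_node(pruned, x) != lab for x, lab in zip(X[hold], y[hold]))
            cv_err[ci] += miss
    cv_rate = cv_err / n
    se = np.sqrt(cv_rate * (1.0 - cv_rate) / n)
    best = int(np.argmin(cv_rate))
    limit = cv_rate[best] + se[best]
    # smallest tree (largest prune level) within one SE of the minimum
    level = max(i for i in range(len(candidates)) if cv_rate[i] <= limit + 1e-12)
    return TreeModel(root=root, prune_level=level, pruned_roots=roots)


def method2_predict(model: TreeModel, features) -> str:
    """Descend the selected tree; ``<=`` goes left."""
    x = np.asarray(
        features.as_array() if hasattr(features, "as_array") else features, dtype=float
    )
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite feature vector {x}")
    return _predict_node(model.active_root(), x)
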