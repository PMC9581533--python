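"""From-scratch CART decision tree with entropy impurity.

Each internal node holds a split ``(j, t)`` sending samples with
``x_j <= t`` left.  Splits are chosen by exhaustive scan over all features
and all midpoints between consecutive distinct sorted values, minimising
the sample-weighted child entropy
``G = (n_left/N) H(left) + (n_right/N) H(right)`` with
``H = -sum_k p_k log2 p_k``.  Recursion stops at purity, at
``min_samples_split``, at ``max_depth`` (default 9) or when no split
reduces the impurity.  Fitting is fully deterministic: ties are broken by
lowest feature index, then lowest threshold, and predicted labels by
lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class TreeHyperparams:
    """Tree settings; the defaults are the tuned values used throughout."""

    criterion: str = "entropy"
    max_depth: int = 9
    min_samples_split: int = 2

    def __post_init__(self) -> None:
        if self.criterion != "entropy":
            raise ValueError("only the entropy criterion is supported")
        if self.max_depth < 1 or self.min_samples_split < 2:
            raise ValueError("bad hyperparameters")


def entropy(proportions) -> float:
    """Shannon entropy in bits, with 0*log(0) = 0."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def best_split(X: np.ndarray, y_idx: np.ndarray, n_classes: int):
    """Exhaustive best split of a node.

    Returns ``(feature, threshold, G)`` minimising the weighted child
    entropy, or ``None`` when every feature is constant (leaf signal).
    ``y_idx`` are class indices in ``range(n_classes)``.
    """
    n, d = X.shape
    best = None  # (G, j, t)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y_idx] = 1.0
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        distinct = xs[1:] > xs[:-1]
        if not np.any(distinct):
            continue
        left = np.cumsum(onehot[order], axis=0)[:-1]  # counts left of each cut
        total = left[-1] + onehot[order[-1]]
        right = total - left
        nl = left.sum(axis=1)
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = left / nl[:, None]
            pr = right / nr[:, None]
            hl = -np.nansum(np.where(pl > 0, pl * np.log2(pl), 0.0), axis=1)
            hr = -np.nansum(np.where(pr > 0, pr * np.log2(pr), 0.0), axis=1)
        g = (nl * hl + nr * hr) / n
        g = np.where(distinct, g, np.inf)
        k = int(np.argmin(g))
        if best is None or g[k] < best[0] - _EPS:
            t = 0.5 * (xs[k] + xs[k + 1])
            best = (float(g[k]), j, float(t))
    if best is None:
        return None
    return best[1], best[2], best[0]


@dataclass
class DecisionNode:
    """One node: a split for internal nodes, class counts everywhere."""

    class_counts: np.ndarray
    depth: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["DecisionNode"] = None
    right: Optional["DecisionNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def proportions(self) -> np.ndarray:
        return self.class_counts / self.class_counts.sum()


@dataclass
class TreeModel:
    """A fitted decision tree with its class labels and feature names."""

    root: DecisionNode
    classes_: np.ndarray
    feature_names: Optional[List[str]] = None
    hyperparams: TreeHyperparams = field(default_factory=TreeHyperparams)
    n_features: int = 0

    def node_count(self) -> int:
        def count(node):
            if node.is_leaf:
                return 1
            return 1 + count(node.left) + count(node.right)
        return count(self.root)


def _grow(X, y_idx, n_classes, depth, hp: TreeHyperparams) -> DecisionNode:
    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    node = DecisionNode(class_counts=counts, depth=depth)
    n = len(y_idx)
    if (n < hp.min_samples_split or depth >= hp.max_depth
            or np.count_nonzero(counts) < 2):
        return node
    found = best_split(X, y_idx, n_classes)
    if found is None:
        return node
    # note: zero-gain splits are allowed (as in standard CART); an impure
    # node such as 2-D XOR needs one gain-free split before any progress
    j, t, g = found
    go_left = X[:, j] <= t
    node.feature = j
    node.threshold = t
    node.left = _grow(X[go_left], y_idx[go_left], n_classes, depth + 1, hp)
    node.right = _grow(X[~go_left], y_idx[~go_left], n_classes, depth + 1, hp)
    return node


def fit_tree(X, y, hp: Optional[TreeHyperparams] = None,
             feature_names: Optional[Sequence[str]] = None,
             seed=None) -> TreeModel:
    """Fit the tree.  Deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic pipeline stages but never used."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    hp = hp or TreeHyperparams()
    classes, y_idx = np.unique(y, return_inverse=True)
    root = _grow(X, y_idx, len(classes), 0, hp)
    return TreeModel(root=root, classes_=classes,
                     feature_names=list(feature_names) if feature_names else None,
                     hyperparams=hp, n_features=X.shape[1])


def _leaf_for(node: DecisionNode, x: np.ndarray) -> DecisionNode:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node


def predict_scores(model: TreeModel, X) -> np.ndarray:
    """Per-class leaf proportions p_mk for each sample (rows sum to 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError("feature count does not match the fitted tree")
    return np.array([_leaf_for(model.root, x).proportions for x in X])


def predict(model: TreeModel, X) -> np.ndarray:
    """Predicted labels: argmax leaf proportion, ties to the lowest label."""
    scores = predict_scores(model, X)
    return model.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# JSON serialisation


def _node_to_dict(node: DecisionNode) -> dict:
    d = {"class_counts": node.class_counts.tolist(), "depth": node.depth}
    if not node.is_leaf:
        d["feature"] = node.feature
        d["threshold"] = node.threshold
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: dict) -> DecisionNode:
    node = DecisionNode(class_counts=np.asarray(d["class_counts"], float),
                        depth=int(d["depth"]))
    if "feature" in d:
        node.feature = int(d["feature"])
        node.threshold = float(d["threshold"])
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def to_json(model: TreeModel) -> str:
    return json.dumps({
        "format": "tpeflim-tree/1",
        "classes": model.classes_.tolist(),
        "feature_names": model.feature_names,
        "n_features": model.n_features,
        "hyperparams": {"criterion": model.hyperparams.criterion,
                        "max_depth": model.hyperparams.max_depth,
                        "min_samples_split": model.hyperparams.min_samples_split},
        "root": _node_to_dict(model.root),
    }, indent=1)


def from_json(text: str) -> TreeModel:
    d = json.loads(text)
    if d.get("format") != "tpeflim-tree/1":
        raise ValueError("not a tpeflim tree model")
    hp = TreeHyperparams(**d["hyperparams"])
    return TreeModel(root=_node_from_dict(d["root"]),
                     classes_=np.asarray(d["classes"]),
                     feature_names=d["feature_names"], hyperparams=hp,
                     n_features=int(d["n_features"]))


def save_model(path, model: TreeModel) -> None:
    with open(path, "w") as f:
        f.write(to_json(model))


def load_model(path) -> TreeModel:
    with open(path) as f:
        return from_json(f.read())
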