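"""A bagged random forest with leaf class-ratio probability averaging.

Each of the T trees (default 10) is grown on a bootstrap sample of the
training pairs.  At every decision node a random subset of
m = max(1, floor(log2(M + 1))) features is drawn and the split with the
best impurity decrease (information gain by default) over candidate
thresholds — midpoints between consecutive distinct values — is taken.
Trees are unpruned: recursion stops only at pure nodes or nodes where no
sampled feature yields an improving split.  A leaf stores the raw class
counts of the training instances that reached it.

A prediction routes the query down every tree, reads each leaf's class-ratio
distribution, and averages the T distributions; the predicted label is the
argmax, with ties broken by the fixed class order of the training set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .descriptors import LAYOUT_VERSION

_GAIN_EPS = 1e-12


@dataclass
class TrainingSet:
    """Feature matrix (rows = pairs) with labels and a fixed class alphabet."""

    features: np.ndarray
    labels: list[str]
    class_set: tuple[str, ...]
    pair_keys: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("row count != label count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("missing or non-finite feature values")
        unknown = set(self.labels) - set(self.class_set)
        if unknown:
            raise ValueError(f"labels outside class_set: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def encoded_labels(self) -> np.ndarray:
        index = {c: k for k, c in enumerate(self.class_set)}
        return np.array([index[l] for l in self.labels], dtype=np.intp)

    def subset(self, rows: Sequence[int]) -> "TrainingSet":
        rows = list(rows)
        return TrainingSet(
            self.features[rows],
            [self.labels[i] for i in rows],
            self.class_set,
            [self.pair_keys[i] for i in rows] if self.pair_keys else None,
        )


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None  # leaf class counts

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class DecisionTree:
    """One unpruned tree; leaves carry raw class-count vectors."""

    root: _Node
    n_classes: int

    def leaf_counts(self, x: np.ndarray) -> np.ndarray:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        assert node.counts is not None
        return node.counts

    def leaf_distribution(self, x: np.ndarray) -> np.ndarray:
        counts = self.leaf_counts(x)
        return counts / counts.sum()

    def predict_label_index(self, x: np.ndarray) -> int:
        return int(np.argmax(self.leaf_counts(x)))

    def n_leaves(self) -> int:
        stack, n = [self.root], 0
        while stack:
            node = stack.pop()
            if node.is_leaf:
                n += 1
            else:
                stack += [node.left, node.right]
        return n


@dataclass
class ForestModel:
    """Trained ensemble: T trees, the per-node feature-subset size m, and
    the fixed class alphabet used for probabilities and tie-breaks."""

    trees: list[DecisionTree]
    m: int
    class_set: tuple[str, ...]
    seed: int
    layout_version: str = LAYOUT_VERSION
    criterion: str = "entropy"
    n_features: int = 0
    oob_accuracy: float | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class Prediction:
    """Per-class probability map with its argmax label."""

    proba: dict[str, float]
    label: str

    @property
    def p(self) -> float:
        return self.proba[self.label]


def attributes_per_node(n_features: int) -> int:
    """The number of candidate features per node: max(1, floor(log2(M+1)))."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return min(n_features, max(1, math.floor(math.log2(n_features + 1))))


def _impurity_rows(counts: np.ndarray, criterion: str) -> np.ndarray:
    """Impurity of each row of a (k, C) count matrix."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    if criterion == "entropy":
        logs = np.log2(p, out=np.zeros_like(p), where=p > 0)
        return -(p * logs).sum(axis=1)
    if criterion == "gini":
        return 1.0 - np.square(p).sum(axis=1)
    raise ValueError(f"unknown criterion: {criterion!r}")


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    candidates: np.ndarray,
    criterion: str,
) -> tuple[int, float] | None:
    """Best (feature, threshold) over candidate features, or None."""
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_imp = _impurity_rows(parent_counts[None, :], criterion)[0]

    best_gain = _GAIN_EPS
    best: tuple[int, float] | None = None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    for f in candidates:
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue
        cum = np.cumsum(onehot[order], axis=0)
        cut = np.nonzero(xs[:-1] < xs[1:])[0]  # split between cut and cut+1
        left = cum[cut]
        right = parent_counts - left
        n_left = (cut + 1).astype(float)
        n_right = n - n_left
        child = (
            n_left * _impurity_rows(left, criterion)
            + n_right * _impurity_rows(right, criterion)
        ) / n
        gains = parent_imp - child
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            best = (int(f), float(0.5 * (xs[cut[k]] + xs[cut[k] + 1])))
    return best


def train_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    m: int,
    rng: np.random.Generator,
    criterion: str = "entropy",
) -> DecisionTree:
    """Grow one unpruned tree on (X, y) with m random features per node."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if len(y) == 0:
        raise ValueError("empty training sample")
    n_features = X.shape[1]
    m = min(m, n_features)

    root = _Node()
    stack: list[tuple[_Node, np.ndarray]] = [(root, np.arange(len(y)))]
    while stack:
        node, rows = stack.pop()
        counts = np.bincount(y[rows], minlength=n_classes).astype(float)
        if np.max(counts) == counts.sum():  # pure
            node.counts = counts
            continue
        candidates = rng.choice(n_features, size=m, replace=False)
        split = _best_split(X[rows], y[rows], n_classes, candidates, criterion)
        if split is None:
            node.counts = counts  # unsplittable (e.g. identical rows)
            continue
        node.feature, node.threshold = split
        mask = X[rows, node.feature] <= node.threshold
        node.left, node.right = _Node(), _Node()
        stack.append((node.left, rows[mask]))
        stack.append((node.right, rows[~mask]))
    return DecisionTree(root, n_classes)


def train_forest(
    data: TrainingSet,
    n_trees: int = 10,
    seed: int = 0,
    criterion: str = "entropy",
    compute_oob: bool = True,
) -> ForestModel:
    """Train the forest: T bootstrap trees, deterministic for a given seed."""
    if n_trees < 1:
        raise ValueError("need at least one tree")
    X = data.features
    y = data.encoded_labels()
    n, n_features = X.shape
    n_classes = len(data.class_set)
    m = attributes_per_node(n_features)

    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)

    trees: list[DecisionTree] = []
    oob_votes = np.zeros((n, n_classes))
    for t in range(n_trees):
        tree_rng = np.random.default_rng(int(tree_seeds[t]))
        sample = tree_rng.integers(0, n, size=n)
        tree = train_tree(X[sample], y[sample], n_classes, m, tree_rng, criterion)
        trees.append(tree)
        if compute_oob:
            out_of_bag = np.setdiff1d(np.arange(n), sample, assume_unique=False)
            for i in out_of_bag:
                oob_votes[i] += tree.leaf_distribution(X[i])

    oob_accuracy = None
    if compute_oob:
        covered = oob_votes.sum(axis=1) > 0
        if covered.any():
            oob_pred = np.argmax(oob_votes[covered], axis=1)
            oob_accuracy = float(np.mean(oob_pred == y[covered]))

    return ForestModel(
        trees=trees,
        m=m,
        class_set=data.class_set,
        seed=seed,
        criterion=criterion,
        n_features=n_features,
        oob_accuracy=oob_accuracy,
    )


def predict_proba(model: ForestModel, x: np.ndarray) -> np.ndarray:
    """Mean of the per-tree leaf class-ratio distributions for one query."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"feature length mismatch: got {x.shape}, expected ({model.n_features},)"
        )
    dist = np.zeros(len(model.class_set))
    for tree in model.trees:
        dist += tree.leaf_distribution(x)
    return dist / model.n_trees


def predict(model: ForestModel, x: np.ndarray) -> Prediction:
    """Predict one pair: averaged probabilities and the argmax label.

    Ties at the maximum resolve to the first class in ``model.class_set``
    order (np.argmax convention).
    """
    proba = predict_proba(model, x)
    label = model.class_set[int(np.argmax(proba))]
    return Prediction(
        proba={c: float(p) for c, p in zip(model.class_set, proba)},
        label=label,
    )


def predict_batch(model: ForestModel, X: np.ndarray) -> list[Prediction]:
    return [predict(model, row) for row in np.asarray(X, dtype=float)]


# ---------------------------------------------------------------------------
# JSON serialization

def _node_to_dict(node: _Node) -> dict:
    if node.is_leaf:
        return {"counts": [float(c) for c in node.counts]}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> _Node:
    if "counts" in d:
        return _Node(counts=np.array(d["counts"], dtype=float))
    return _Node(
        feature=d["feature"],
        threshold=d["threshold"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def model_to_json(model: ForestModel) -> str:
    payload = {
        "format": "sseforest-model",
        "version": 1,
        "layout_version": model.layout_version,
        "class_set": list(model.class_set),
        "m": model.m,
        "seed": model.seed,
        "criterion": model.criterion,
        "n_features": model.n_features,
        "oob_accuracy": model.oob_accuracy,
        "trees": [_node_to_dict(t.root) for t in model.trees],
    }
    return json.dumps(payload)


def model_from_json(text: str) -> ForestModel:
    payload = json.loads(text)
    if payload.get("format") != "sseforest-model":
        raise ValueError("not a sseforest model document")
    class_set = tuple(payload["class_set"])
    trees = [
        DecisionTree(_node_from_dict(d), len(class_set)) for d in payload["trees"]
    ]
    return ForestModel(
        trees=trees,
        m=payload["m"],
        class_set=class_set,
        seed=payload["seed"],
        layout_version=payload["layout_version"],
        criterion=payload["criterion"],
        n_features=payload["n_features"],
        oob_accuracy=payload.get("oob_accuracy"),
    )
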