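"""Binary CART decision tree with Gini impurity, built from scratch.

The classifier is a depth-bounded recursive binary partitioner over a
document-term matrix.  At every node it searches exhaustively over all
features, with candidate thresholds at the midpoints between consecutive
distinct sorted feature values, and takes the split with the largest
count-weighted Gini impurity decrease.  Ties are broken deterministically
(lowest feature index, then lowest threshold) and a leaf with an even
class split predicts the negative class, so training is a pure function
of the data.

Split comparison is done in exact integer arithmetic.  For a split into
(left, right) with class counts ``(ql, pl)`` / ``(qr, pr)``, maximizing
the impurity decrease is equivalent to maximizing

    S = (pl^2 + ql^2) / nl + (pr^2 + qr^2) / nr,

a ratio of integers; candidate splits are compared by cross
multiplication, so floating-point rounding can never flip a tie-break.
Default maximum depth is 15.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

MODEL_SCHEMA_VERSION = 1

DEFAULT_MAX_DEPTH = 15


@dataclass(frozen=True)
class TrainConfig:
    max_depth: int = DEFAULT_MAX_DEPTH
    min_samples_split: int = 2
    random_seed: int = 0  # kept for interface symmetry; training is deterministic

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")


@dataclass(frozen=True)
class Leaf:
    counts: tuple[int, int]  # (n_negative, n_positive) training rows routed here
    prediction: int  # 0 = negative, 1 = positive


@dataclass(frozen=True)
class Node:
    feature: int
    threshold: float
    left: "Node | Leaf"
    right: "Node | Leaf"


@dataclass(frozen=True)
class DecisionTreeModel:
    root: Node | Leaf
    n_features: int
    depth: int
    config: TrainConfig


@dataclass(frozen=True)
class SplitChoice:
    feature: int
    threshold: float
    decrease: float  # count-weighted Gini impurity decrease


def gini(class_counts: Sequence[int]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a two-class count pair."""
    a, b = class_counts
    if a < 0 or b < 0:
        raise ValueError("class counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("gini undefined for an empty node")
    return 1.0 - ((a / total) ** 2 + (b / total) ** 2)


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X)


def best_split(
    X, y, features: Sequence[int] | None = None
) -> SplitChoice | None:
    """Exhaustive best Gini split, or None if no split has positive decrease.

    Thresholds are midpoints between consecutive distinct sorted values;
    rows with value <= threshold go left.  Ties in impurity decrease are
    broken by lowest feature index, then lowest threshold.
    """
    X = _dense(X)
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    pos = int(y.sum())
    neg = n - pos
    if features is None:
        features = range(X.shape[1])
    # best = (A, B, feature, threshold); the score is the fraction A/B
    best: tuple[int, int, int, float] | None = None
    for f in features:
        v = X[:, f]
        order = np.argsort(v, kind="stable")
        sv = v[order]
        sy = y[order]
        boundaries = np.nonzero(sv[1:] > sv[:-1])[0]
        if boundaries.size == 0:
            continue
        cum_pos = np.cumsum(sy)
        nl = (boundaries + 1).astype(np.int64)
        pl = cum_pos[boundaries].astype(np.int64)
        ql = nl - pl
        nr = n - nl
        pr = pos - pl
        qr = nr - pr
        A = (pl * pl + ql * ql) * nr + (pr * pr + qr * qr) * nl
        B = nl * nr
        # float pre-screen, then exact comparison among near-maximal candidates
        S = A / B
        near = np.nonzero(S >= S.max() - 1e-9 * max(1.0, S.max()))[0]
        chosen: tuple[int, int, int] | None = None
        for i in near:
            a, b = int(A[i]), int(B[i])
            if chosen is None or a * chosen[1] > chosen[0] * b:
                chosen = (a, b, int(i))
        assert chosen is not None
        a, b, i = chosen
        k = int(boundaries[i])
        threshold = (float(sv[k]) + float(sv[k + 1])) / 2.0
        if best is None or a * best[1] > best[0] * b:
            best = (a, b, int(f), threshold)
    if best is None:
        return None
    a, b, f, threshold = best
    # decrease > 0  <=>  A/B > (pos^2 + neg^2) / n, checked exactly
    if a * n <= (pos * pos + neg * neg) * b:
        return None
    parent = gini((neg, pos))
    decrease = parent - (1.0 - (a / b) / n)
    return SplitChoice(f, threshold, decrease)


def _majority(neg: int, pos: int) -> int:
    return 1 if pos > neg else 0  # tie -> negative


def _build(X: np.ndarray, y: np.ndarray, depth: int, config: TrainConfig):
    n = y.size
    pos = int(y.sum())
    neg = n - pos
    leaf = Leaf((neg, pos), _majority(neg, pos))
    if pos == 0 or neg == 0 or depth >= config.max_depth or n < config.min_samples_split:
        return leaf, 0
    choice = best_split(X, y)
    if choice is None:
        return leaf, 0
    mask = X[:, choice.feature] <= choice.threshold
    left, dl = _build(X[mask], y[mask], depth + 1, config)
    right, dr = _build(X[~mask], y[~mask], depth + 1, config)
    return Node(choice.feature, choice.threshold, left, right), max(dl, dr) + 1


def train(X, y, config: TrainConfig | None = None) -> DecisionTreeModel:
    """Fit a depth-bounded CART tree on {0, 1} labels.

    Recursion stops at node purity, at ``max_depth``, below
    ``min_samples_split`` rows, or when no split yields a positive
    impurity decrease.  Leaves predict the majority class; an exact tie
    predicts negative.
    """
    if config is None:
        config = TrainConfig()
    X = _dense(X)
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("cannot train on an empty set")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be encoded as 0 (negative) / 1 (positive)")
    root, depth = _build(X, y, 0, config)
    return DecisionTreeModel(root, X.shape[1], depth, config)


def _max_feature(node) -> int:
    if isinstance(node, Leaf):
        return -1
    return max(node.feature, _max_feature(node.left), _max_feature(node.right))


def predict(model: DecisionTreeModel, X) -> np.ndarray:
    """Route each row through the tree (value <= threshold goes left)."""
    X = _dense(X)
    if X.shape[1] <= _max_feature(model.root):
        raise ValueError(
            f"matrix has {X.shape[1]} columns but the model splits on feature "
            f"{_max_feature(model.root)}"
        )
    out = np.empty(X.shape[0], dtype=np.int64)
    for i in range(X.shape[0]):
        node = model.root
        while isinstance(node, Node):
            node = node.left if X[i, node.feature] <= node.threshold else node.right
        out[i] = node.prediction
    return out


# ---------------------------------------------------------------------------
# JSON serialization

def _node_to_obj(node):
    if isinstance(node, Leaf):
        return {"kind": "leaf", "counts": list(node.counts), "prediction": node.prediction}
    return {
        "kind": "split",
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_obj(node.left),
        "right": _node_to_obj(node.right),
    }


def _node_from_obj(obj):
    if obj["kind"] == "leaf":
        return Leaf(tuple(obj["counts"]), obj["prediction"])
    return Node(
        obj["feature"],
        obj["threshold"],
        _node_from_obj(obj["left"]),
        _node_from_obj(obj["right"]),
    )


def to_json(model: DecisionTreeModel) -> str:
    return json.dumps(
        {
            "schema_version": MODEL_SCHEMA_VERSION,
            "n_features": model.n_features,
            "depth": model.depth,
            "config": {
                "max_depth": model.config.max_depth,
                "min_samples_split": model.config.min_samples_split,
                "random_seed": model.config.random_seed,
            },
            "root": _node_to_obj(model.root),
        },
        indent=2,
    )


def from_json(text: str) -> DecisionTreeModel:
    obj = json.loads(text)
    if obj.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {obj.get('schema_version')!r}")
    return DecisionTreeModel(
        _node_from_obj(obj["root"]),
        obj["n_features"],
        obj["depth"],
        TrainConfig(**obj["config"]),
    )


def save_model(model: DecisionTreeModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_json(model))


def load_model(path) -> DecisionTreeModel:
    with open(path, encoding="utf-8") as fh:
        return from_json(fh.read())
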