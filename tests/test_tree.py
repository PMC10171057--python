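"""From-scratch CART tree: split search, training, prediction, serialization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from reportriage import tree
from reportriage.reference import ref_predict, ref_structure, ref_train
from reportriage.tree import Leaf, Node, TrainConfig, best_split, gini, predict, train


def tree_structure(node):
    if isinstance(node, Leaf):
        return ("leaf", node.prediction)
    return (
        "split",
        node.feature,
        float(node.threshold),
        tree_structure(node.left),
        tree_structure(node.right),
    )


# ---------------------------------------------------------------------------
# gini

@pytest.mark.parametrize(
    "counts,expected",
    [((5, 0), 0.0), ((4, 4), 0.5), ((2, 6), 0.375), ((0, 3), 0.0)],
)
def test_gini_values(counts, expected):
    assert gini(counts) == pytest.approx(expected)


def test_gini_empty_node_errors():
    with pytest.raises(ValueError):
        gini((0, 0))


# ---------------------------------------------------------------------------
# best_split

def test_separable_single_feature():
    X = np.array([[0], [0], [1], [1]])
    y = np.array([0, 0, 1, 1])
    choice = best_split(X, y)
    assert choice.feature == 0
    assert choice.threshold == pytest.approx(0.5)
    assert choice.decrease == pytest.approx(0.5)


def test_pure_labels_give_no_split():
    X = np.array([[0], [1], [2]])
    assert best_split(X, np.array([1, 1, 1])) is None


def test_tied_features_break_to_lower_index():
    X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
    y = np.array([0, 0, 1, 1])
    assert best_split(X, y).feature == 0


def test_tied_thresholds_break_to_lower_threshold():
    # both midpoints 0.5 and 1.5 separate one pure group of equal size
    X = np.array([[0], [1], [2]])
    y = np.array([0, 1, 0])
    choice = best_split(X, y)
    assert choice.threshold == pytest.approx(0.5)


def test_constant_feature_unsplittable():
    X = np.array([[3], [3], [3]])
    assert best_split(X, np.array([0, 1, 0])) is None


# ---------------------------------------------------------------------------
# train / predict

def test_linearly_separable_fits_depth_one():
    X = np.array([[0], [0], [1], [1]])
    y = np.array([0, 0, 1, 1])
    model = train(X, y)
    assert model.depth == 1
    assert (predict(model, X) == y).all()


def test_xor_with_depth_one_cap():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    y = np.array([0, 1, 1, 0])
    model = train(X, y, TrainConfig(max_depth=1))
    assert model.depth <= 1
    assert (predict(model, X) == y).mean() <= 0.75


def test_single_class_training_set_is_single_leaf():
    model = train(np.array([[0], [1]]), np.array([1, 1]))
    assert isinstance(model.root, Leaf)
    assert model.root.prediction == 1


def test_empty_training_set_errors():
    with pytest.raises(ValueError):
        train(np.empty((0, 2)), np.array([], dtype=int))


def test_leaf_tie_predicts_negative():
    model = train(np.array([[0], [0]]), np.array([0, 1]))
    assert isinstance(model.root, Leaf)
    assert model.root.prediction == 0


def test_hand_built_tree_prediction():
    root = Node(
        feature=1,
        threshold=0.5,
        left=Leaf((3, 0), 0),
        right=Node(feature=0, threshold=2.0, left=Leaf((0, 2), 1), right=Leaf((1, 0), 0)),
    )
    model = tree.DecisionTreeModel(root, n_features=2, depth=2, config=TrainConfig())
    probes = np.array([[9, 0], [1, 1], [5, 1]])
    assert predict(model, probes).tolist() == [0, 1, 0]


def test_single_leaf_model_constant_prediction():
    model = train(np.array([[0], [1], [2]]), np.array([0, 0, 0]))
    assert predict(model, np.array([[5], [-1]])).tolist() == [0, 0]


def test_predict_feature_out_of_range_errors():
    model = train(np.array([[0, 1], [1, 0], [0, 0], [1, 1]]), np.array([1, 0, 0, 1]))
    with pytest.raises(ValueError):
        predict(model, np.array([[1]]))


def test_sparse_input_accepted():
    import scipy.sparse as sp

    X = sp.csr_matrix(np.array([[0], [0], [1], [1]]))
    model = train(X, np.array([0, 0, 1, 1]))
    assert predict(model, X).tolist() == [0, 0, 1, 1]


def test_default_config():
    config = TrainConfig()
    assert config.max_depth == 15
    assert config.min_samples_split == 2


# ---------------------------------------------------------------------------
# oracle equivalence with the naive exhaustive reference

def test_matches_reference_on_all_tiny_binary_instances():
    for rows, cols in itertools.product(range(1, 4), range(1, 3)):
        for bits in itertools.product([0, 1], repeat=rows * cols):
            X = np.array(bits, dtype=np.int64).reshape(rows, cols)
            for labels in itertools.product([0, 1], repeat=rows):
                y = np.array(labels, dtype=np.int64)
                model = train(X, y)
                ref = ref_train([list(r) for r in X], list(labels), max_depth=15)
                assert tree_structure(model.root) == ref_structure(ref)


def test_matches_reference_on_random_instances():
    rng = np.random.default_rng(42)
    probes = np.array(list(itertools.product([0, 1], repeat=3)), dtype=np.int64)
    for _ in range(60):
        n = int(rng.integers(4, 9))
        X = rng.integers(0, 2, size=(n, 3)).astype(np.int64)
        y = rng.integers(0, 2, size=n).astype(np.int64)
        model = train(X, y)
        ref = ref_train([list(r) for r in X], list(y), max_depth=15)
        assert tree_structure(model.root) == ref_structure(ref)
        assert predict(model, probes).tolist() == [ref_predict(ref, list(p)) for p in probes]


def test_agrees_with_sklearn_on_separable_data():
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(7)
    X = rng.integers(0, 3, size=(120, 6)).astype(np.int64)
    y = (X[:, 0] + X[:, 3] >= 3).astype(np.int64)
    model = train(X, y)
    ours = (predict(model, X) == y).mean()
    sk = DecisionTreeClassifier(criterion="gini", max_depth=15, random_state=0).fit(X, y)
    theirs = sk.score(X, y)
    assert ours == pytest.approx(theirs)
    assert ours == 1.0


# ---------------------------------------------------------------------------
# properties

@given(
    arrays(np.int64, shape=st.tuples(st.integers(2, 12), st.integers(1, 4)),
           elements=st.integers(0, 3)),
    st.integers(1, 4),
    st.integers(0, 1),
)
@settings(max_examples=60)
def test_depth_bound_never_exceeded(X, max_depth, parity):
    y = (X.sum(axis=1) % 2 == parity).astype(np.int64)
    model = train(X, y, TrainConfig(max_depth=max_depth))
    assert model.depth <= max_depth


@given(
    arrays(np.int64, shape=st.tuples(st.integers(4, 12), st.integers(1, 3)),
           elements=st.integers(0, 2)),
)
@settings(max_examples=40)
def test_training_accuracy_non_decreasing_in_depth(X):
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=X.shape[0]).astype(np.int64)
    accs = []
    for depth in (1, 2, 4, 8):
        model = train(X, y, TrainConfig(max_depth=depth))
        accs.append((predict(model, X) == y).mean())
    assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))


@given(
    arrays(np.int64, shape=st.tuples(st.integers(2, 10), st.integers(1, 3)),
           elements=st.integers(0, 2)),
    st.integers(1, 5),
)
@settings(max_examples=40)
def test_prediction_invariant_to_appended_zero_columns(X, extra):
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=X.shape[0]).astype(np.int64)
    model = train(X, y)
    padded = np.hstack([X, np.zeros((X.shape[0], extra), dtype=np.int64)])
    assert predict(model, X).tolist() == predict(model, padded).tolist()


def test_json_roundtrip():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 3, size=(30, 4)).astype(np.int64)
    y = rng.integers(0, 2, size=30).astype(np.int64)
    model = train(X, y)
    restored = tree.from_json(tree.to_json(model))
    assert tree_structure(restored.root) == tree_structure(model.root)
    assert (predict(restored, X) == predict(model, X)).all()
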