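"""Tree induction, prediction, size accounting and serialization."""
import numpy as np
import pytest

from bvroctree import (
    Dataset,
    Internal,
    Leaf,
    NodeModel,
    PlantedPair,
    SynthSpec,
    Tree,
    TreeConfig,
    TreeSchemaError,
    fit,
    generate,
    tree_size,
)
from bvroctree.exceptions import InputError


def leaf_paths(tree):
    """(path feature sets, leaves) for every root-to-leaf path."""
    out = []

    def walk(node, used):
        if isinstance(node, Leaf):
            out.append((used, node))
            return
        walk(node.left, used | set(node.model.feature_indices))
        walk(node.right, used | set(node.model.feature_indices))

    walk(tree.root, set())
    return out


def test_pure_data_yields_single_leaf():
    data = Dataset(matrix=np.random.default_rng(0).standard_normal((5, 4)),
                   labels=np.ones(5, dtype=int))
    tree = fit(data)
    assert isinstance(tree.root, Leaf)
    assert tree.root.label == 1
    assert tree_size(tree) == 0


@pytest.mark.parametrize("seed", range(5))
def test_recovers_planted_pair_small(seed):
    """One perfectly-separating planted pair among 50 genes, n=40."""
    spec = SynthSpec(n_samples=40, n_genes=50,
                     planted_pairs=(PlantedPair(genes=(3, 17)),), seed=seed)
    data, truth = generate(spec)
    tree = fit(data)
    assert tree_size(tree) == 1
    assert set(tree.root.model.feature_indices) == set(truth.pairs[0].genes)
    assert np.all(tree.predict(data.matrix) == data.labels)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sequential_signals_give_small_tree(seed):
    """Two half-sample signals need a couple of splits; size stays in 2-3.

    Each signal gene separates the classes in one half of the samples and
    is noise in the other, so no single node resolves everything; the
    stopping AUC then caps growth after a few splits.
    """
    rng = np.random.default_rng(seed)
    n = 40
    y = rng.permuted(np.r_[-np.ones(20), np.ones(20)]).astype(int)
    half = np.arange(n) < 20
    X = rng.standard_normal((n, 80))
    X[:, 2] = np.where(half, 2.0 * y, rng.normal(0, 2.5, n))
    X[:, 6] = np.where(~half, 2.0 * y, rng.normal(0, 2.5, n))
    tree = fit(Dataset(matrix=X, labels=y))
    assert 2 <= tree_size(tree) <= 3


def hand_tree():
    model = NodeModel(
        feature_indices=(0, 1),
        coefficients=np.array([1.0, 1.0]),
        derived=np.empty(0),
        auc=1.0,
        threshold=0.0,
    )
    return Tree(
        root=Internal(
            model=model,
            left=Leaf(label=1, class_counts=(0, 4), score=1.0),
            right=Leaf(label=-1, class_counts=(3, 1), score=0.25),
        ),
        config=TreeConfig(),
        feature_names=["gA", "gB"],
    )


def test_predict_hand_built_rule():
    tree = hand_tree()
    assert tree.predict(np.array([[2.0, -1.0]]))[0] == 1  # 1 > 0 -> left
    assert tree.predict(np.array([[-2.0, 1.0]]))[0] == -1  # -1 <= 0 -> right
    assert tree.predict(np.array([[0.0, 0.0]]))[0] == -1  # boundary goes right


def test_predict_score_is_leaf_proportion():
    tree = hand_tree()
    scores = tree.predict_score(np.array([[2.0, 0.0], [-2.0, 0.0]]))
    assert scores == pytest.approx([1.0, 0.25])


def test_single_leaf_tree_predicts_constantly():
    tree = Tree(root=Leaf(label=-1, class_counts=(4, 0), score=0.0),
                config=TreeConfig(), feature_names=["g"])
    assert np.all(tree.predict(np.zeros((7, 1))) == -1)
    assert tree.predict_score(np.zeros((7, 1))) == pytest.approx(np.zeros(7))
    assert tree_size(tree) == 0


def test_tree_size_counts_internal_nodes():
    t1 = hand_tree()
    assert tree_size(t1) == 1
    nested = Tree(
        root=Internal(model=t1.root.model, left=t1.root, right=t1.root.right),
        config=TreeConfig(),
        feature_names=["gA", "gB"],
    )
    assert tree_size(nested) == 2


def test_resubstitution_and_partition_on_noisy_fit(rng):
    X = rng.standard_normal((30, 20))
    y = rng.choice([-1, 1], size=30)
    y[:2] = [-1, 1]
    data = Dataset(matrix=X, labels=y)
    tree = fit(data)
    # every sample reaches exactly one leaf; leaf counts partition the data
    total = sum(sum(leaf.class_counts) for _, leaf in leaf_paths(tree))
    assert total == 30
    # no gene reused along any root-to-leaf path
    def check_paths(node, used):
        if isinstance(node, Leaf):
            return
        assert not (set(node.model.feature_indices) & used)
        nxt = used | set(node.model.feature_indices)
        check_paths(node.left, nxt)
        check_paths(node.right, nxt)
    check_paths(tree.root, set())
    # prediction agrees with the stored leaf the sample trained into
    preds = tree.predict(data.matrix)
    assert set(np.unique(preds)) <= {-1, 1}


def test_stop_mode_leaf_skips_the_split():
    spec = SynthSpec(n_samples=40, n_genes=50,
                     planted_pairs=(PlantedPair(genes=(3, 17)),), seed=1)
    data, _ = generate(spec)
    tree = fit(data, TreeConfig(stop_mode="leaf", stop_auc=0.5))
    assert isinstance(tree.root, Leaf)


def test_serialization_round_trip(rng):
    spec = SynthSpec(n_samples=40, n_genes=30,
                     planted_pairs=(PlantedPair(genes=(3, 17)),), seed=2)
    data, _ = generate(spec)
    tree = fit(data)
    clone = Tree.from_json(tree.to_json())
    queries = rng.standard_normal((100, data.n_genes))
    assert np.array_equal(tree.predict(queries), clone.predict(queries))
    assert tree.predict_score(queries) == pytest.approx(
        clone.predict_score(queries), abs=0
    )
    assert clone.config == tree.config
    text = tree.render_text()
    assert "leaf" in text and "g0003" in text or "g0017" in text


def test_schema_version_and_truncation_errors():
    tree = hand_tree()
    payload = tree.to_dict()
    payload["version"] = 99
    with pytest.raises(TreeSchemaError):
        Tree.from_dict(payload)
    with pytest.raises(TreeSchemaError):
        Tree.from_json(tree.to_json()[: len(tree.to_json()) // 2])
    with pytest.raises(TreeSchemaError):
        Tree.from_dict({"format": "something-else"})


def test_missing_feature_value_raises():
    tree = hand_tree()
    with pytest.raises(InputError):
        tree.predict(np.array([[np.nan, 1.0]]))


def test_input_errors():
    with pytest.raises(InputError):
        fit(Dataset(matrix=np.empty((3, 0)), labels=np.array([-1, 1, 1]),
                    feature_names=[], sample_ids=["a", "b", "c"]))
    with pytest.raises(InputError):
        Dataset(matrix=np.ones((2, 2)), labels=np.array([0, 1]))
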