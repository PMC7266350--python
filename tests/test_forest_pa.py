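"""Forest-PA: weight ranges, penalized CART, diversity, degeneracy to bagging."""

import math

import numpy as np
import pytest

from circgcn import PaForest, predict_proba, train_forest, weight_range
from circgcn.forest_pa import (
    AttributeWeightState,
    PaTree,
    build_tree,
    forest_from_json,
    forest_to_json,
    merit,
    update_weights,
)


# ------------------------------------------------------------ weight range
def test_weight_range_root_level():
    assert weight_range(1, 0.01) == (0.0, pytest.approx(math.exp(-1)))


def test_weight_range_level_two():
    lo, hi = weight_range(2, 0.01)
    assert lo == pytest.approx(math.exp(-1) + 0.01)
    assert hi == pytest.approx(math.exp(-0.5))


def test_weight_range_upper_bound_increases_toward_one():
    uppers = [weight_range(lam, 1e-9)[1] for lam in range(1, 30)]
    assert all(b > a for a, b in zip(uppers, uppers[1:]))
    assert uppers[-1] < 1.0


def test_weight_range_empty_interval_rejected():
    with pytest.raises(ValueError, match="empty"):
        weight_range(10, 0.01)


def test_merit_is_damped_gain():
    assert merit(0.4, 0.5) == pytest.approx(0.2)
    assert merit(0.4, 1.0) == 0.4
    assert merit(0.0, 0.3) == 0.0


# ------------------------------------------------------- reference CART
def _reference_cart(x, y, n_classes, min_leaf=2):
    """Plain unweighted CART grown with an explicit per-threshold scan."""

    def gini(counts):
        n = counts.sum()
        if n == 0:
            return 0.0
        p = counts / n
        return 1.0 - (p * p).sum()

    tree = PaTree()

    def grow(idx, depth):
        counts = np.bincount(y[idx], minlength=n_classes).astype(float)
        node = tree.n_nodes
        tree.feature.append(-1)
        tree.threshold.append(0.0)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.dist.append((counts / counts.sum()).tolist())
        if (counts > 0).sum() <= 1 or idx.size < 2 * min_leaf:
            return node
        best = (-np.inf, None, None)
        parent = gini(counts)
        for f in range(x.shape[1]):
            vals = np.unique(x[idx, f])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = idx[x[idx, f] <= thr]
                right = idx[x[idx, f] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                g = parent - (
                    len(left) * gini(np.bincount(y[left], minlength=n_classes).astype(float))
                    + len(right) * gini(np.bincount(y[right], minlength=n_classes).astype(float))
                ) / idx.size
                if g > best[0] + 1e-15:
                    best = (g, f, thr)
        if best[1] is None or best[0] <= 0:
            return node
        _, f, thr = best
        tree.feature[node] = f
        tree.threshold[node] = thr
        lam = depth + 1
        if f not in tree.tested_attribute_levels or lam < tree.tested_attribute_levels[f]:
            tree.tested_attribute_levels[f] = lam
        tree.left[node] = grow(idx[x[idx, f] <= thr], depth + 1)
        tree.right[node] = grow(idx[x[idx, f] > thr], depth + 1)
        return node

    grow(np.arange(x.shape[0]), 0)
    return tree


def _blobs(seed=0, n=60, d=4, sep=2.5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, d))
    b = rng.normal(0, 1, (n, d))
    b[:, 0] += sep
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


def test_unit_weights_reproduce_reference_cart():
    x, y = _blobs(seed=2)
    ours = build_tree(x, y, weights=np.ones(x.shape[1]))
    ref = _reference_cart(x, y, n_classes=2)
    assert ours.feature == ref.feature
    assert ours.threshold == pytest.approx(ref.threshold)
    assert ours.dist == ref.dist


def test_separable_1d_gives_depth_one_perfect_tree():
    x = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
    y = np.array([0, 0, 0, 1, 1, 1])
    tree = build_tree(x, y, weights=np.ones(1), min_leaf=1)
    assert tree.feature[0] == 0
    assert tree.n_nodes == 3  # root + two pure leaves
    pred = tree.apply(x).argmax(axis=1)
    assert np.array_equal(pred, y)


def test_penalization_can_move_the_root_split():
    """A near-zero weight on the informative attribute lets a weaker one win."""
    rng = np.random.default_rng(4)
    x = np.column_stack([np.repeat([0.0, 1.0], 30), rng.random(60)])
    y = np.repeat([0, 1], 30)
    free = build_tree(x, y, weights=np.array([1.0, 1.0]))
    assert free.feature[0] == 0
    penalized = build_tree(x, y, weights=np.array([1e-6, 1.0]))
    assert penalized.feature[0] == 1


def test_update_weights_rules():
    tree = PaTree(tested_attribute_levels={0: 1, 2: 3})
    state = AttributeWeightState(
        weight=np.array([0.4, 0.9, 0.8]),
        increment=np.array([0.0, 0.2, 0.0]),
        rho=0.01,
        n_trees=10,
    )
    new = update_weights(state, tree, np.random.default_rng(0))
    lo0, hi0 = weight_range(1, 0.01)
    lo2, hi2 = weight_range(3, 0.01)
    assert lo0 <= new.weight[0] <= hi0
    assert lo2 <= new.weight[2] <= hi2
    assert new.increment[0] == pytest.approx((1 - new.weight[0]) / 10)
    # untested attribute recovers by its increment, capped at 1
    assert new.weight[1] == pytest.approx(1.0)


def test_untested_attributes_unchanged_by_empty_tree():
    tree = PaTree()  # no splits recorded
    state = AttributeWeightState(
        weight=np.array([0.5, 0.7]), increment=np.array([0.1, 0.0]), rho=0.01
    )
    new = update_weights(state, tree, np.random.default_rng(0))
    assert new.weight == pytest.approx([0.6, 0.7])


# ----------------------------------------------------------------- forest
def test_penalty_off_equals_bagged_reference_cart_tree_for_tree():
    x, y = _blobs(seed=5, n=40)
    forest = train_forest(x, y, n_trees=5, seed=9, penalize=False)
    rng = np.random.default_rng(9)
    for tree in forest.trees:
        boot = rng.integers(0, x.shape[0], size=x.shape[0])
        ref = _reference_cart(x[boot], y[boot], n_classes=2)
        assert tree.feature == ref.feature
        assert tree.threshold == pytest.approx(ref.threshold)


def test_forest_deterministic_and_rejects_single_class():
    x, y = _blobs(seed=1, n=30)
    f1 = train_forest(x, y, n_trees=4, seed=3)
    f2 = train_forest(x, y, n_trees=4, seed=3)
    for t1, t2 in zip(f1.trees, f2.trees):
        assert t1.feature == t2.feature and t1.threshold == t2.threshold
    with pytest.raises(ValueError):
        train_forest(x, np.zeros_like(y), n_trees=2, seed=0)


def test_penalized_forest_diversifies_root_attributes():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(120, 6))
    y = ((x[:, 0] + 0.8 * x[:, 1] + 0.6 * x[:, 2]) > 0).astype(int)
    forest = train_forest(x, y, n_trees=20, seed=1, penalize=True)
    roots = {t.feature[0] for t in forest.trees if t.feature[0] >= 0}
    assert len(roots) >= 2


def test_holdout_accuracy_on_separable_blobs():
    x, y = _blobs(seed=8, n=100)
    xt, yt = _blobs(seed=9, n=50)
    forest = train_forest(x, y, n_trees=30, seed=0)
    acc = (predict_proba(forest, xt)[:, 1] >= 0.5).astype(int)
    assert (acc == yt).mean() > 0.9


def test_predict_proba_rows_normalized_and_vote_averaging():
    leaf0 = PaTree(feature=[-1], threshold=[0.0], left=[-1], right=[-1], dist=[[1.0, 0.0]])
    leaf1 = PaTree(feature=[-1], threshold=[0.0], left=[-1], right=[-1], dist=[[0.0, 1.0]])
    forest = PaForest(trees=[leaf0, leaf1], n_classes=2, seed=0, rho=0.01)
    probs = predict_proba(forest, np.zeros((3, 2)))
    assert np.allclose(probs, 0.5)
    with pytest.raises(ValueError):
        predict_proba(PaForest(trees=[], n_classes=2, seed=0, rho=0.01), np.zeros((1, 2)))


def test_serialization_round_trip(tmp_path):
    x, y = _blobs(seed=3, n=30)
    forest = train_forest(x, y, n_trees=3, seed=2)
    path = tmp_path / "forest.json"
    forest_to_json(forest, path)
    loaded = forest_from_json(path)
    assert np.allclose(predict_proba(forest, x), predict_proba(loaded, x))
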