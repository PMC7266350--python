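"""Sampled graph convolution: exactness, unbiasedness, training behavior."""

import math

import numpy as np
import pytest

from circgcn import (
    GcnConfig,
    GcnModel,
    build_sample_graph,
    extract_features,
    full_layer,
    sampled_layer,
    train_fastgcn,
)
from circgcn.fastgcn import (
    _backward,
    _ce_loss_and_grad,
    _sampled_forward,
    batch_loss,
    importance_distribution,
    relu,
)


def _random_graph(n, seed, d=3):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    a = (a + a.T) / 2
    feats = rng.normal(size=(n, d))
    return a, feats


# ---------------------------------------------------------------- layers
def test_full_layer_identity_and_row_mean():
    h = np.array([[1.0], [3.0]])
    assert np.array_equal(full_layer(h, np.eye(2), np.eye(1)), h)
    a = np.array([[0.5, 0.5], [0.5, 0.5]])
    assert np.allclose(full_layer(h, a, np.array([[1.0]])), [[2.0], [2.0]])


def test_full_layer_relu_rectifies():
    h = np.array([[1.0], [1.0]])
    out = full_layer(h, np.eye(2), np.array([[-2.0]]), activation=relu)
    assert np.array_equal(out, np.zeros((2, 1)))


def test_full_layer_shape_mismatch():
    with pytest.raises(ValueError):
        full_layer(np.ones((2, 3)), np.eye(2), np.ones((2, 1)))


@pytest.mark.parametrize("seed", range(4))
def test_exhaustive_sampling_equals_full_propagation(seed):
    a, h = _random_graph(10, seed)
    w = np.random.default_rng(seed + 100).normal(size=(3, 2))
    q = importance_distribution(a, "uniform")
    s = sampled_layer(h, a, w, q, t=10, seed=0, exhaustive=True)
    assert np.abs(s - full_layer(h, a, w)).max() < 1e-10


def test_sampled_layer_deterministic_given_seed():
    a, h = _random_graph(6, 2)
    w = np.ones((3, 1))
    q = importance_distribution(a, "importance")
    s1 = sampled_layer(h, a, w, q, t=4, seed=42)
    s2 = sampled_layer(h, a, w, q, t=4, seed=42)
    assert np.array_equal(s1, s2)


def test_importance_sampling_unbiased():
    """Mean sampled pre-activation over many draws matches the exact layer."""
    a, h = _random_graph(5, 0)
    w = np.random.default_rng(1).normal(size=(3, 2))
    exact = full_layer(h, a, w)
    q = importance_distribution(a, "importance")
    rng = np.random.default_rng(7)
    draws = 10_000
    acc = np.zeros_like(exact)
    acc2 = np.zeros_like(exact)
    for _ in range(draws):
        s = sampled_layer(h, a, w, q, t=3, seed=rng)
        acc += s
        acc2 += s**2
    mean = acc / draws
    se = np.sqrt(np.maximum(acc2 / draws - mean**2, 0) / draws)
    assert (np.abs(mean - exact) < 4 * se + 1e-9).all()


def test_importance_beats_uniform_variance_on_hub_graph():
    """Column-norm proposal reduces estimator variance when the kernel mass
    concentrates on a high-degree hub (uniform draws waste samples on columns
    that contribute nothing; the proposal spends them all on the hub)."""
    n = 12
    a = np.zeros((n, n))
    a[:, 0] = 1.0  # hub column carries all kernel mass
    a[0, :] = 0.0
    a[0, 0] = 1.0
    h = np.random.default_rng(0).normal(size=(n, 2))
    w = np.eye(2)
    var = {}
    for mode in ("uniform", "importance"):
        q = importance_distribution(a, mode)
        rng = np.random.default_rng(3)
        outs = np.array([sampled_layer(h, a, w, q, t=4, seed=rng) for _ in range(2000)])
        var[mode] = outs.var(axis=0).mean()
    assert var["importance"] <= var["uniform"]


def test_zero_mass_on_active_column_warns():
    a = np.eye(3)
    q = importance_distribution(a, "uniform")
    q.q = np.array([0.5, 0.5, 0.0])
    with pytest.warns(RuntimeWarning, match="zero mass"):
        sampled_layer(np.ones((3, 1)), a, np.ones((1, 1)), q, t=2, seed=0)


# ----------------------------------------------------------- sample graph
def test_identical_features_give_complete_uniform_graph():
    g = build_sample_graph(np.ones((3, 4)), k=2)
    assert np.allclose(g.a_hat, 1.0 / 3.0)


def test_saturated_k_gives_dense_graph():
    rng = np.random.default_rng(0)
    g = build_sample_graph(rng.random((5, 3)), k=4)
    assert (g.a_hat > 0).all()


def test_self_loops_always_present():
    g = build_sample_graph(np.eye(4), k=1)
    assert (np.diag(g.a_hat) > 0).all()


def test_graph_k_validation():
    with pytest.raises(ValueError):
        build_sample_graph(np.eye(3), k=0)
    with pytest.raises(ValueError):
        build_sample_graph(np.eye(3), k=3)


# ------------------------------------------------------------- batch loss
def _toy_graph(n=8, seed=0):
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(n, 4))
    g = build_sample_graph(feats, k=3)
    labels = (np.arange(n) % 2).astype(int)
    return g, labels


def test_batch_loss_uniform_predictor_is_log2():
    g, labels = _toy_graph()
    cfg = GcnConfig(hidden_dims=(), sample_sizes=(8,), epochs=0, seed=0)
    model = GcnModel(weights=[np.zeros((4, 2))], config=cfg)
    loss = batch_loss(model, g, labels, np.arange(8), seed=0, exhaustive=True)
    assert loss == pytest.approx(math.log(2))


def test_batch_loss_exhaustive_matches_full_propagation():
    g, labels = _toy_graph()
    rng = np.random.default_rng(1)
    w0, w1 = rng.normal(size=(4, 3)), rng.normal(size=(3, 2))
    cfg = GcnConfig(hidden_dims=(3,), sample_sizes=(8, 8), epochs=0, seed=0)
    model = GcnModel(weights=[w0, w1], config=cfg)
    loss = batch_loss(model, g, labels, np.arange(8), seed=0, exhaustive=True)
    # full propagation by hand
    h1 = relu(g.a_hat @ g.features @ w0)
    logits = g.a_hat @ h1 @ w1
    manual, _ = _ce_loss_and_grad(logits, labels, 2)
    assert loss == pytest.approx(manual)


def test_batch_loss_rejects_empty_and_non_train_batches():
    g, labels = _toy_graph()
    g.train_mask[0] = False
    cfg = GcnConfig(hidden_dims=(), sample_sizes=(8,), epochs=0)
    model = GcnModel(weights=[np.zeros((4, 2))], config=cfg)
    with pytest.raises(ValueError):
        batch_loss(model, g, labels, np.array([]), seed=0)
    with pytest.raises(ValueError):
        batch_loss(model, g, labels, np.array([0]), seed=0)


def test_manual_gradients_match_finite_differences():
    """Backprop through the exhaustive two-layer forward vs numeric gradients."""
    g, labels = _toy_graph(n=6, seed=3)
    rng = np.random.default_rng(2)
    weights = [rng.normal(size=(4, 3)), rng.normal(size=(3, 2))]
    q = importance_distribution(g.a_hat, "uniform")
    batch = np.arange(6)

    def loss_of(ws):
        logits, _ = _sampled_forward(
            ws, g, batch, q, (6, 6), np.random.default_rng(0), relu, exhaustive=True
        )
        return _ce_loss_and_grad(logits, labels, 2)[0]

    logits, cache = _sampled_forward(
        weights, g, batch, q, (6, 6), np.random.default_rng(0), relu, exhaustive=True
    )
    _, dlogits = _ce_loss_and_grad(logits, labels, 2)
    grads = _backward(cache, weights, dlogits, "relu")

    eps = 1e-6
    for li in range(2):
        for idx in [(0, 0), (1, 1), (2, 0)]:
            pert = [w.copy() for w in weights]
            pert[li][idx] += eps
            up = loss_of(pert)
            pert[li][idx] -= 2 * eps
            down = loss_of(pert)
            numeric = (up - down) / (2 * eps)
            assert grads[li][idx] == pytest.approx(numeric, abs=1e-5)


# --------------------------------------------------------------- training
def _blobs_graph(seed=0, n_per=40):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.4, size=(n_per, 6)) + np.array([2, 0, 0, 0, 0, 0])
    b = rng.normal(0, 0.4, size=(n_per, 6)) + np.array([0, 2, 0, 0, 0, 0])
    feats = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return build_sample_graph(feats, k=5), labels


def test_training_beats_uniform_predictor_on_separable_blobs():
    g, labels = _blobs_graph()
    cfg = GcnConfig(epochs=100, batch_size=32, sample_sizes=(40, 40), seed=1)
    model = train_fastgcn(g, labels, cfg)
    assert model.loss_trace[-1] < math.log(2)


def test_zero_epochs_returns_initial_weights():
    g, labels = _blobs_graph()
    cfg = GcnConfig(epochs=0, sample_sizes=(16, 16), seed=5)
    model = train_fastgcn(g, labels, cfg)
    from circgcn.fastgcn import _init_weights

    expected = _init_weights(cfg, g.features.shape[1], np.random.default_rng(5))
    for w, e in zip(model.weights, expected):
        assert np.array_equal(w, e)


def test_training_deterministic_given_seed():
    g, labels = _blobs_graph()
    cfg = GcnConfig(epochs=10, batch_size=32, sample_sizes=(32, 32), seed=3)
    m1 = train_fastgcn(g, labels, cfg)
    m2 = train_fastgcn(g, labels, cfg)
    for a, b in zip(m1.weights, m2.weights):
        assert np.array_equal(a, b)


def test_single_class_training_rejected():
    g, labels = _blobs_graph()
    with pytest.raises(ValueError, match="single class"):
        train_fastgcn(g, np.zeros_like(labels), GcnConfig(epochs=1, sample_sizes=(8, 8)))


def test_non_train_labels_never_influence_weights():
    g, labels = _blobs_graph()
    g.train_mask = np.zeros(g.n, dtype=bool)
    g.train_mask[::2] = True
    cfg = GcnConfig(epochs=15, batch_size=32, sample_sizes=(32, 32), seed=2)
    m1 = train_fastgcn(g, labels, cfg)
    flipped = labels.copy()
    flipped[~g.train_mask] = 1 - flipped[~g.train_mask]
    m2 = train_fastgcn(g, flipped, cfg)
    for a, b in zip(m1.weights, m2.weights):
        assert np.array_equal(a, b)


def test_extracted_feature_shapes_and_degenerate_depth():
    g, labels = _blobs_graph()
    cfg = GcnConfig(hidden_dims=(16,), epochs=5, batch_size=32, sample_sizes=(32, 32), seed=0)
    model = train_fastgcn(g, labels, cfg)
    feats = extract_features(model, g)
    assert feats.shape == (g.n, 16)
    cfg1 = GcnConfig(hidden_dims=(), epochs=0, sample_sizes=(8,), seed=0)
    model1 = train_fastgcn(g, labels, cfg1)
    assert np.array_equal(extract_features(model1, g), g.features)


def test_identical_nodes_get_identical_embeddings():
    feats = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    g = build_sample_graph(feats, k=1)
    labels = np.array([0, 0, 1, 1])
    model = train_fastgcn(g, labels, GcnConfig(epochs=5, batch_size=4, sample_sizes=(4, 4), seed=0))
    emb = extract_features(model, g)
    assert np.allclose(emb[0], emb[1])
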