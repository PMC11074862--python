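"""Classifier tests: convolution oracle, pooling, forward invariances,
training behaviour."""

import math

import numpy as np
import pytest

from diffconn.nn import (AttentionGCN, ModelConfig, gcn_layer,
                         self_attention_pool, topk_indices)


def random_graph(rng, n, p=0.3):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


def dense_oracle(features, adjacency, weights):
    """Explicitly form D~^{-1/2}(A+I)D~^{-1/2} and multiply, loop-free of
    the library helper."""
    n = adjacency.shape[0]
    a_t = adjacency.astype(float) + np.eye(n)
    d = np.diag(1.0 / np.sqrt(a_t.sum(axis=1)))
    return np.maximum(d @ a_t @ d @ features @ weights, 0.0)


class TestGcnLayer:
    def test_isolated_node_reduces_to_relu_of_xw(self):
        out = gcn_layer(np.array([[1.0, -1.0]]), np.zeros((1, 1)), np.eye(2))
        assert np.allclose(out, [[1.0, 0.0]])

    def test_symmetry_of_equivalent_nodes(self):
        a = np.array([[0, 1], [1, 0]])
        x = np.array([[0.5, 0.2], [0.5, 0.2]])
        out = gcn_layer(x, a, np.eye(2))
        assert np.allclose(out[0], out[1])

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            a = random_graph(rng, n)
            x = rng.normal(size=(n, 4))
            w = rng.normal(size=(4, 3))
            assert np.allclose(gcn_layer(x, a, w), dense_oracle(x, a, w),
                               atol=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(np.ones((3, 2)), np.zeros((4, 4)), np.eye(2))


class TestPooling:
    @pytest.mark.parametrize("n", list(range(1, 201)))
    def test_keeps_ceil_ratio_nodes(self, n):
        rng = np.random.default_rng(n)
        a = random_graph(rng, n) if n > 1 else np.zeros((1, 1), dtype=int)
        x = rng.normal(size=(n, 3))
        w = rng.normal(size=3)
        _, _, idx, _ = self_attention_pool(x, a, w, ratio=0.35)
        assert len(idx) == math.ceil(0.35 * n)

    def test_ratio_one_keeps_all_and_scales_by_scores(self):
        rng = np.random.default_rng(0)
        n = 6
        a = random_graph(rng, n)
        x = rng.normal(size=(n, 3))
        w = rng.normal(size=3)
        pooled, sub, idx, scores = self_attention_pool(x, a, w, ratio=1.0)
        assert np.array_equal(idx, np.arange(n))
        assert np.array_equal(sub, a)
        assert np.allclose(pooled, x * scores[:, None])

    def test_hand_set_scores_select_expected_nodes(self):
        # isolated nodes: propagation is the identity, so choosing
        # x = atanh(s) makes the scores exactly s
        target = np.array([0.9, 0.1, 0.8, 0.2])
        x = np.arctanh(target)[:, None]
        _, _, idx, scores = self_attention_pool(
            x, np.zeros((4, 4)), np.array([1.0]), ratio=0.5)
        assert np.allclose(scores, target, atol=1e-12)
        assert np.array_equal(idx, [0, 2])

    def test_ties_break_toward_lower_index(self):
        s = np.array([[0.5, 0.7, 0.5, 0.1]])
        assert np.array_equal(topk_indices(s, 2)[0], [0, 1])

    def test_n116_keeps_41(self):
        rng = np.random.default_rng(1)
        a = random_graph(rng, 116)
        x = rng.normal(size=(116, 2))
        _, _, idx, _ = self_attention_pool(x, a, rng.normal(size=2), ratio=0.35)
        assert len(idx) == 41


def straight_line_forward(model, X, A):
    """Independent per-graph reimplementation of the forward pass."""
    p, cfg = model.params, model.config
    n = A.shape[0]

    def norm(a):
        at = a.astype(float) + np.eye(a.shape[0])
        dinv = np.diag(1.0 / np.sqrt(at.sum(1)))
        return dinv @ at @ dinv

    out = []
    for x in X:
        h1 = np.maximum(norm(A) @ x @ p["W1"] + p["b1"], 0.0)
        s1 = np.tanh(norm(A) @ (h1 @ p["ws1"] + p["bs1"][0]))
        k1 = math.ceil(cfg.pool_ratio * n)
        keep1 = np.sort(np.argsort(-s1, kind="stable")[:k1])
        x1 = h1[keep1] * s1[keep1, None]
        a1 = A[np.ix_(keep1, keep1)]
        h2 = np.maximum(norm(a1) @ x1 @ p["W2"] + p["b2"], 0.0)
        s2 = np.tanh(norm(a1) @ (h2 @ p["ws2"] + p["bs2"][0]))
        k2 = math.ceil(cfg.pool_ratio * k1)
        keep2 = np.sort(np.argsort(-s2, kind="stable")[:k2])
        x2 = h2[keep2] * s2[keep2, None]
        slots = np.zeros((n, x2.shape[1]))
        slots[keep1[keep2]] = x2
        out.append(slots.reshape(-1) @ p["Wh"] + p["bh"])
    return np.stack(out)


class TestForward:
    def _setup(self, seed=0, n=12, f=12, b=3):
        rng = np.random.default_rng(seed)
        A = random_graph(rng, n)
        X = rng.normal(size=(b, n, f))
        model = AttentionGCN(f, ModelConfig(channels=(6, 4), seed=2), n_nodes=n)
        return model, X, A

    def test_matches_independent_reimplementation(self):
        model, X, A = self._setup()
        assert np.allclose(model.forward(X, A),
                           straight_line_forward(model, X, A), atol=1e-8)

    def test_duplicated_graphs_get_identical_logits(self):
        model, X, A = self._setup()
        batch = np.concatenate([X[:1], X[:1], X[1:2]])
        logits = model.forward(batch, A)
        assert np.allclose(logits[0], logits[1])

    def test_zero_features_give_equal_logits(self):
        model, X, A = self._setup()
        logits = model.forward(np.zeros_like(X), A)
        assert np.allclose(logits, logits[0])

    def test_batch_order_invariance(self):
        model, X, A = self._setup(b=5)
        perm = [3, 0, 4, 1, 2]
        assert np.allclose(model.forward(X, A)[perm],
                           model.forward(X[perm], A), atol=1e-10)

    def test_empty_batch_rejected(self):
        model, X, A = self._setup()
        with pytest.raises(ValueError, match="empty"):
            model.forward(X[:0], A)


def separable_samples(rng, count=40, n=20, delta=1.5):
    """Linearly separable toy graphs: class shifts a block of entries."""
    A = random_graph(rng, n, p=0.25)
    X, y = [], []
    for k in range(count):
        label = k % 2
        x = rng.normal(scale=0.3, size=(n, n))
        x[2, 5] = x[5, 2] = 0.2 + delta * label + rng.normal(scale=0.1)
        x[3, 7] = x[7, 3] = 0.2 + delta * label + rng.normal(scale=0.1)
        X.append(x)
        y.append(label)
    return np.stack(X), np.array(y), A


class TestTraining:
    def test_separable_fixture_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(5)
        X, y, A = separable_samples(rng)
        cfg = ModelConfig(epochs=200, seed=0, batch_size=16)
        model = AttentionGCN(X.shape[2], cfg, n_nodes=X.shape[1]).fit(X, y, A)
        assert (model.predict(X, A) == y).mean() == 1.0

    def test_permuted_labels_stay_at_chance_on_heldout(self):
        rng = np.random.default_rng(6)
        X, y, A = separable_samples(rng, count=120)
        y_perm = rng.permutation(y)
        cfg = ModelConfig(epochs=60, seed=0, batch_size=16, n_restarts=0)
        model = AttentionGCN(X.shape[2], cfg, n_nodes=X.shape[1])
        model.fit(X[:60], y_perm[:60], A)
        acc = (model.predict(X[60:], A) == y_perm[60:]).mean()
        assert 0.3 <= acc <= 0.7

    def test_same_seed_reproduces_weights(self):
        rng = np.random.default_rng(7)
        X, y, A = separable_samples(rng, count=20)
        cfg = ModelConfig(epochs=10, seed=3)
        m1 = AttentionGCN(X.shape[2], cfg, n_nodes=X.shape[1]).fit(X, y, A)
        m2 = AttentionGCN(X.shape[2], cfg, n_nodes=X.shape[1]).fit(X, y, A)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self):
        rng = np.random.default_rng(8)
        X, _, A = separable_samples(rng, count=6)
        model = AttentionGCN(X.shape[2], ModelConfig(epochs=1),
                             n_nodes=X.shape[1])
        with pytest.raises(ValueError, match="single class"):
            model.fit(X, np.zeros(6, dtype=int), A)

    def test_smoothed_loss_trace_is_monotone(self):
        rng = np.random.default_rng(9)
        X, y, A = separable_samples(rng, count=20)
        model = AttentionGCN(X.shape[2], ModelConfig(epochs=30, seed=1),
                             n_nodes=X.shape[1]).fit(X, y, A)
        sm = model.smoothed_loss_trace()
        assert np.all(np.diff(sm) <= 0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X, y, A = separable_samples(rng, count=12)
        model = AttentionGCN(X.shape[2], ModelConfig(epochs=5, seed=4),
                             n_nodes=X.shape[1]).fit(X, y, A)
        model.save(tmp_path / "ckpt")
        back = AttentionGCN.load(tmp_path / "ckpt")
        assert np.allclose(model.forward(X, A), back.forward(X, A), atol=1e-10)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        n, f = 9, 5
        A = random_graph(rng, n)
        X = rng.normal(size=(4, n, f))
        y = np.array([0, 1, 1, 0])
        model = AttentionGCN(f, ModelConfig(channels=(4, 3), seed=1), n_nodes=n)
        logits, cache = model.forward(X, A, cache=True)
        loss, dlog = model._loss_grad(logits, y)
        grads, dX = model.backward(cache, dlog)
        eps = 1e-6
        for key in ("W1", "ws1", "W2", "ws2", "Wh", "b1", "bh"):
            w = model.params[key]
            flat = np.argwhere(np.ones_like(np.atleast_1d(w)))
            for idx in flat[:: max(1, len(flat) // 5)]:
                idx = tuple(idx) if w.ndim > 1 else int(idx[0])
                orig = w[idx]
                w[idx] = orig + eps
                lp = model._loss_grad(model.forward(X, A), y)[0]
                w[idx] = orig - eps
                lm = model._loss_grad(model.forward(X, A), y)[0]
                w[idx] = orig
                assert grads[key][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                        abs=1e-6)
        b, i, j = 1, 4, 2
        orig = X[b, i, j]
        X[b, i, j] = orig + eps
        lp = model._loss_grad(model.forward(X, A), y)[0]
        X[b, i, j] = orig - eps
        lm = model._loss_grad(model.forward(X, A), y)[0]
        X[b, i, j] = orig
        assert dX[b, i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)
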