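import numpy as np
import pytest
from hypothesis import given, strategies as st

from omicsfusion.layers import (
    AttentionParams,
    SubNetworkParams,
    attention_normalize,
    attention_scores,
    dense_embedding_forward,
    dense_layer_forward,
    fuse_and_predict,
    graph_embedding_forward,
    identity,
    init_attention_params,
    init_subnetwork_params,
    kill_matrix,
    relu,
    subnetwork_forward,
)


# -- explicit-loop oracles ---------------------------------------------------

def _dense_oracle(x, W, b, f):
    out = np.empty(W.shape[1])
    for j in range(W.shape[1]):
        acc = b[j]
        for i in range(W.shape[0]):
            acc += W[i, j] * x[i]
        out[j] = acc
    return f(out)


def _graph_oracle(x, W, A, b, f):
    return _dense_oracle(x, W * A, b, f)


def _softmax_oracle(W3, k):
    n_d, M, n_f = W3.shape
    out = np.zeros_like(W3)
    for d in range(n_d):
        for i in range(n_f):
            denom = sum(np.exp(W3[d, m, i]) for m in range(M))
            for m in range(M):
                out[d, m, i] = np.exp(W3[d, m, i]) * k[d, i] / denom
    return out


class TestDenseEmbedding:
    def test_zero_weights(self):
        assert np.all(dense_embedding_forward(np.ones(3), np.zeros((3, 2)),
                                              np.zeros(2)) == 0)

    def test_identity_passthrough(self, rng):
        x = rng.standard_normal(4)
        out = dense_embedding_forward(x, np.eye(4), np.zeros(4), identity)
        np.testing.assert_allclose(out, x)

    def test_worked_example(self):
        x = np.array([1.0, 2.0])
        W = np.array([[1.0, 0.0], [1.0, 1.0]])
        b = np.array([0.5, -10.0])
        np.testing.assert_allclose(
            dense_embedding_forward(x, W, b, relu), [3.5, 0.0]
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dense_embedding_forward(np.ones(3), np.zeros((2, 2)), np.zeros(2))


class TestGraphEmbedding:
    def test_worked_example(self):
        x = np.array([1.0, 2.0, 3.0])
        W = np.ones((3, 3))
        A = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        out = graph_embedding_forward(x, W, A, np.zeros(3), identity)
        np.testing.assert_allclose(out, [3.0, 3.0, 3.0])

    def test_all_ones_mask_equals_dense(self, rng):
        # mask identity over 1000 random trials, dims <= 20
        for _ in range(1000):
            n = int(rng.integers(1, 21))
            x = rng.standard_normal(n)
            W = rng.standard_normal((n, n))
            b = rng.standard_normal(n)
            np.testing.assert_allclose(
                graph_embedding_forward(x, W, np.ones((n, n)), b),
                dense_embedding_forward(x, W, b),
                atol=1e-15,
            )

    def test_mask_blocks_information_exhaustively(self, rng):
        """Output unit j must depend only on inputs i with A[i, j] = 1
        (exhaustive perturbation, dims <= 10)."""
        for n in range(2, 11):
            A = (rng.random((n, n)) < 0.5).astype(float)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 1.0)
            W = rng.standard_normal((n, n))
            b = rng.standard_normal(n)
            x = rng.standard_normal(n)
            base = graph_embedding_forward(x, W, A, b, identity)
            for i in range(n):
                xp = x.copy()
                xp[i] += 1.7
                out = graph_embedding_forward(xp, W, A, b, identity)
                changed = np.abs(out - base) > 1e-12
                assert not np.any(changed & (A[i] == 0))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            graph_embedding_forward(np.ones(3), np.ones((3, 3)),
                                    np.ones((2, 2)), np.zeros(3))


class TestDenseLayer:
    def test_zero_weights_give_activated_bias(self):
        out = dense_layer_forward(np.ones(2), np.zeros((2, 2)),
                                  np.array([1.0, -1.0]), relu)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_worked_example(self):
        y1 = np.array([1.0, -1.0])
        W2 = np.array([[2.0, 0.0], [0.0, 2.0]])
        b2 = np.array([0.0, 1.0])
        np.testing.assert_allclose(dense_layer_forward(y1, W2, b2, relu),
                                   [2.0, 0.0])


class TestOracleEquivalence:
    def test_embeddings_match_explicit_loops(self, rng):
        for _ in range(120):
            n, e = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            x = rng.standard_normal(n)
            W = rng.standard_normal((n, e))
            b = rng.standard_normal(e)
            np.testing.assert_allclose(
                dense_embedding_forward(x, W, b, relu),
                _dense_oracle(x, W, b, relu), atol=1e-12)
            Wsq = rng.standard_normal((n, n))
            A = (rng.random((n, n)) < 0.5).astype(float)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 1.0)
            bs = rng.standard_normal(n)
            np.testing.assert_allclose(
                graph_embedding_forward(x, Wsq, A, bs, relu),
                _graph_oracle(x, Wsq, A, bs, relu), atol=1e-12)

    def test_attention_normalize_matches_explicit_loop(self, rng):
        for _ in range(100):
            n_d, M = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            W3 = rng.standard_normal((n_d, M, n_d)) * 3
            k = kill_matrix(n_d, n_d)
            np.testing.assert_allclose(attention_normalize(W3, k),
                                       _softmax_oracle(W3, k), atol=1e-12)


class TestSubnetwork:
    def test_all_zero_weights_give_head_bias(self):
        p = SubNetworkParams(np.zeros((3, 3)), np.zeros(3), None,
                             np.zeros((3, 2)), np.zeros(2),
                             np.zeros((2, 4)), np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(subnetwork_forward(np.ones(3), p),
                                   [1.0, 2.0, 3.0, 4.0])

    def test_inference_deterministic(self, rng):
        p = init_subnetwork_params(5, 3, 2, rng, dropout_embed=0.5,
                                   dropout_hidden=0.5)
        x = rng.standard_normal((4, 5))
        np.testing.assert_array_equal(subnetwork_forward(x, p),
                                      subnetwork_forward(x, p))

    def test_composition_matches_per_layer_oracles(self, rng):
        n, h, d = 2, 3, 2
        p = init_subnetwork_params(n, h, d, rng)
        x = rng.standard_normal(n)
        y1 = _dense_oracle(x, p.W1, p.b1, relu)
        y2 = _dense_oracle(y1, p.W2, p.b2, relu)
        head = _dense_oracle(y2, p.Wh, p.bh, identity)
        np.testing.assert_allclose(subnetwork_forward(x, p), head, atol=1e-12)

    def test_graph_kind_requires_square(self, rng):
        with pytest.raises(ValueError):
            SubNetworkParams(np.zeros((3, 2)), np.zeros(2), np.eye(3),
                             np.zeros((2, 2)), np.zeros(2),
                             np.zeros((2, 2)), np.zeros(2))


class TestAttention:
    def test_uniform_raw_weights(self):
        W3 = np.zeros((4, 3, 4))
        W = attention_normalize(W3)
        for d in range(4):
            np.testing.assert_allclose(W[d, :, d], [1 / 3] * 3)
            off = [i for i in range(4) if i != d]
            assert np.all(W[d][:, off] == 0)

    def test_single_omics_weight_one(self):
        W = attention_normalize(np.ones((3, 1, 3)) * 2.5)
        for d in range(3):
            assert W[d, 0, d] == pytest.approx(1.0)

    def test_log3_softmax_example(self):
        W3 = np.zeros((1, 2, 1))
        W3[0, 0, 0] = np.log(3.0)
        W = attention_normalize(W3)
        np.testing.assert_allclose(W[0, :, 0], [0.75, 0.25])

    def test_normalization_holds_at_extremes(self, rng):
        # arbitrary finite raw weights, including +/-50 extremes
        W3 = rng.uniform(-50, 50, size=(6, 4, 6))
        W3[0, :, 0] = [50, -50, 50, -50]
        W = attention_normalize(W3)
        k = kill_matrix(6, 6)
        np.testing.assert_allclose(W.sum(axis=1), k, atol=1e-12)
        assert np.all(np.isfinite(W))

    def test_matches_naive_formula_when_safe(self, rng):
        W3 = rng.standard_normal((3, 3, 3))
        naive = np.exp(W3) / np.exp(W3).sum(axis=1, keepdims=True)
        naive = naive * kill_matrix(3, 3)[:, None, :]
        np.testing.assert_allclose(attention_normalize(W3), naive, atol=1e-14)

    def test_monotonicity_of_scores(self, rng):
        W3 = rng.standard_normal((5, 4, 5))
        s0 = attention_scores(attention_normalize(W3))
        W3b = W3.copy()
        W3b[2, 1, 2] += 0.5
        s1 = attention_scores(attention_normalize(W3b))
        assert s1[1, 2] > s0[1, 2]
        others = [m for m in range(4) if m != 1]
        assert np.all(s1[others, 2] <= s0[others, 2] + 1e-15)


class TestFuseAndPredict:
    def _att(self, W3, b=None):
        n_d = W3.shape[0]
        return AttentionParams(W3, np.zeros(n_d) if b is None else b)

    def test_single_head_passthrough(self, rng):
        head = rng.standard_normal(4)
        att = self._att(np.zeros((4, 1, 4)))
        np.testing.assert_allclose(fuse_and_predict([head], att), head)

    def test_hand_arithmetic_example(self):
        heads = [np.array([1.0, 2.0]), np.array([3.0, 6.0])]
        W3 = np.zeros((2, 2, 2))
        W3[0, 0, 0] = np.log(3.0)     # drug 1 weights (0.75, 0.25)
        # drug 2 weights stay (0.5, 0.5)
        att = self._att(W3)
        np.testing.assert_allclose(fuse_and_predict(heads, att), [1.5, 4.0])

    def test_equal_heads_fixed_point(self, rng):
        v = rng.standard_normal(3)
        b = rng.standard_normal(3)
        att = AttentionParams(rng.standard_normal((3, 4, 3)), b)
        heads = [v.copy() for _ in range(4)]
        np.testing.assert_allclose(fuse_and_predict(heads, att), v + b, atol=1e-12)

    def test_convex_combination_bounds(self, rng):
        for _ in range(50):
            M, n_d = int(rng.integers(1, 5)), int(rng.integers(1, 6))
            heads = [rng.standard_normal(n_d) for _ in range(M)]
            att = AttentionParams(rng.standard_normal((n_d, M, n_d)), np.zeros(n_d))
            y = fuse_and_predict(heads, att)
            stacked = np.stack(heads)
            assert np.all(y >= stacked.min(axis=0) - 1e-12)
            assert np.all(y <= stacked.max(axis=0) + 1e-12)

    def test_head_size_mismatch_raises(self):
        att = self._att(np.zeros((3, 2, 3)))
        with pytest.raises(ValueError):
            fuse_and_predict([np.zeros(2), np.zeros(2)], att)


class TestAttentionScores:
    def test_uniform_scores(self):
        W = attention_normalize(np.zeros((4, 5, 4)))
        np.testing.assert_allclose(attention_scores(W), np.full((5, 4), 0.2))

    def test_worked_column(self):
        W3 = np.zeros((1, 2, 1))
        W3[0, 0, 0] = np.log(3.0)
        s = attention_scores(attention_normalize(W3))
        np.testing.assert_allclose(s[:, 0], [0.75, 0.25])

    def test_columns_sum_to_one_thousand_draws(self, rng):
        for _ in range(1000):
            W3 = rng.standard_normal((3, 4, 3)) * 5
            s = attention_scores(attention_normalize(W3))
            np.testing.assert_allclose(s.sum(axis=0), 1.0, atol=1e-12)


def test_kill_matrix_identity_pattern():
    k = kill_matrix(3, 3)
    np.testing.assert_array_equal(k, np.eye(3))


def test_attention_params_requires_nf_equal_nd():
    with pytest.raises(ValueError):
        AttentionParams(np.zeros((3, 2, 4)), np.zeros(3))


def test_glorot_init_shapes(rng):
    p = init_subnetwork_params(6, 4, 3, rng, embedding_size=5)
    assert p.W1.shape == (6, 5) and p.W2.shape == (5, 4) and p.Wh.shape == (4, 3)
    assert np.all(p.b1 == 0) and np.all(p.b2 == 0) and np.all(p.bh == 0)
    a = init_attention_params(4, 2, rng)
    assert a.W3.shape == (4, 2, 4) and np.all(a.b == 0)
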