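"""Encoder stages against explicit-loop oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import calfuse as cf
from calfuse._autodiff import Tensor
from calfuse.encoder import (CrossModalEncoder, EncoderConfig,
                             cross_modal_attention, init_params, predict,
                             softmax_probs)

RNG = np.random.default_rng(7)


def _model(dims=(3, 2), K=2, h=4, L=1, heads=1, seed=0, dropout=0.0):
    cfg = EncoderConfig(modality_dims=dims, n_classes=K, embed_dim=h,
                        n_layers=L, n_heads=heads, dropout_rate=dropout,
                        seed=seed)
    return CrossModalEncoder(cfg)


# ---------------------------------------------------------------------------
# embedding and positional encoding
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_zero_weights_give_zero_tokens(self):
        m = _model()
        for p in ("emb0_W", "emb0_b", "emb1_W", "emb1_b"):
            m.params[p].data[:] = 0.0
        H = m.embed_modalities([RNG.standard_normal((4, 3)),
                                RNG.standard_normal((4, 2))])
        np.testing.assert_array_equal(H.data, 0.0)

    def test_identity_weights_reduce_to_nonlinearity(self):
        m = _model(dims=(4,), K=2, h=4)
        m.params["emb0_W"].data = np.eye(4)
        m.params["emb0_b"].data[:] = 0.0
        x = RNG.standard_normal((3, 4))
        H = m.embed_modalities([x])
        np.testing.assert_allclose(H.data[:, 0, :], np.tanh(x), atol=1e-12)

    def test_tiny_weights_match_hand_arithmetic(self):
        m = _model(dims=(2,), K=2, h=2)
        m.params["emb0_W"].data = np.array([[0.5, -1.0], [2.0, 0.25]])
        m.params["emb0_b"].data = np.array([0.1, -0.2])
        H = m.embed_modalities([np.array([[1.0, 2.0]])])
        expected = np.tanh([0.5 + 4.0 + 0.1, -1.0 + 0.5 - 0.2])
        np.testing.assert_allclose(H.data[0, 0], expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = _model()
        with pytest.raises(ValueError, match="manifest"):
            m.embed_modalities([RNG.standard_normal((4, 5)),
                                RNG.standard_normal((4, 2))])

    def test_missing_values_rejected_before_imputation(self):
        m = _model()
        x = RNG.standard_normal((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="imput"):
            m.embed_modalities([x, RNG.standard_normal((4, 2))])


class TestPositionalEncoding:
    def test_zero_p_is_identity_and_zero_h_returns_p(self):
        m = _model()
        H = Tensor(RNG.standard_normal((4, 2, 4)))
        m.params["pos"].data[:] = 0.0
        np.testing.assert_array_equal(m.add_positional_encoding(H).data, H.data)
        m.params["pos"].data = RNG.standard_normal((2, 4))
        zero = Tensor(np.zeros((4, 2, 4)))
        np.testing.assert_array_equal(
            m.add_positional_encoding(zero).data,
            np.broadcast_to(m.params["pos"].data, (4, 2, 4)))

    def test_elementwise_sum_on_toy(self):
        m = _model(dims=(2, 2), h=2)
        m.params["pos"].data = np.array([[1.0, 2.0], [3.0, 4.0]])
        H = Tensor(np.array([[[10.0, 20.0], [30.0, 40.0]]]))
        np.testing.assert_array_equal(m.add_positional_encoding(H).data,
                                      [[[11.0, 22.0], [33.0, 44.0]]])


# ---------------------------------------------------------------------------
# transformer layers: oracle equivalence
# ---------------------------------------------------------------------------

def loop_transformer_layer(H, p, layer, n_heads, eps=1e-5):
    """Explicit-loop single-layer reference: MHSA + FFN, both residual+LN."""
    n, M, h = H.shape
    dk = h // n_heads
    out = np.empty_like(H)
    for s in range(n):
        x = H[s]
        q = x @ p[f"layer{layer}_Wq"].data
        k = x @ p[f"layer{layer}_Wk"].data
        v = x @ p[f"layer{layer}_Wv"].data
        att = np.zeros((M, h))
        for head in range(n_heads):
            sl = slice(head * dk, (head + 1) * dk)
            scores = np.empty((M, M))
            for i in range(M):
                for j in range(M):
                    scores[i, j] = q[i, sl] @ k[j, sl] / np.sqrt(dk)
            for i in range(M):
                e = np.exp(scores[i] - scores[i].max())
                w = e / e.sum()
                for j in range(M):
                    att[i, sl] += w[j] * v[j, sl]
        att = att @ p[f"layer{layer}_Wo"].data
        x = x + att
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        x = ((x - mu) / np.sqrt(var + eps) * p[f"layer{layer}_lna_g"].data
             + p[f"layer{layer}_lna_b"].data)
        ff = (np.maximum(x @ p[f"layer{layer}_ff_W1"].data
                         + p[f"layer{layer}_ff_b1"].data, 0.0)
              @ p[f"layer{layer}_ff_W2"].data + p[f"layer{layer}_ff_b2"].data)
        x2 = x + ff
        mu = x2.mean(axis=1, keepdims=True)
        var = x2.var(axis=1, keepdims=True)
        out[s] = ((x2 - mu) / np.sqrt(var + eps) * p[f"layer{layer}_lnb_g"].data
                  + p[f"layer{layer}_lnb_b"].data)
    return out


class TestTransformerEncode:
    def test_single_layer_single_head_matches_loop_oracle(self):
        m = _model(dims=(2, 2), h=2, L=1, heads=1, seed=13)
        H = Tensor(RNG.standard_normal((3, 2, 2)))
        got = m.transformer_encode(H).data
        want = loop_transformer_layer(H.data, m.params, 0, n_heads=1)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_multi_head_three_tokens_matches_loop_oracle(self):
        m = _model(dims=(2, 2, 2), h=4, L=2, heads=2, seed=14)
        H = Tensor(RNG.standard_normal((4, 3, 4)))
        got = m.transformer_encode(H).data
        want = H.data
        for l in range(2):
            want = loop_transformer_layer(want, m.params, l, n_heads=2)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_single_modality_attention_is_identity(self):
        m = _model(dims=(3,), h=4, heads=2)
        H = Tensor(RNG.standard_normal((2, 1, 4)))
        record = {}
        m.transformer_encode(H, record=record)
        for w in record["self_attention"]:
            np.testing.assert_allclose(w, 1.0)  # 1x1 softmax

    def test_attention_rows_sum_to_one(self):
        m = _model(dims=(2, 2, 2), h=4, heads=2)
        H = Tensor(RNG.standard_normal((5, 3, 4)))
        record = {}
        m.transformer_encode(H, record=record)
        for w in record["self_attention"]:
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_non_finite_activations_fail_fast(self):
        m = _model()
        m.params["layer0_ff_W1"].data[:] = 1e300
        m.params["layer0_ff_W2"].data[:] = 1e300
        with pytest.raises(FloatingPointError):
            m.transformer_encode(Tensor(RNG.standard_normal((2, 2, 4)) + 10))


# ---------------------------------------------------------------------------
# cross-modality attention
# ---------------------------------------------------------------------------

class TestCrossModalAttention:
    def test_zero_query_projection_gives_mean_of_values(self):
        H_i = RNG.standard_normal((3, 4))
        H_j = RNG.standard_normal((5, 4))
        W_V = RNG.standard_normal((4, 4))
        c = cross_modal_attention(H_i, H_j, np.zeros((4, 4)),
                                  RNG.standard_normal((4, 4)), W_V, d_k=4)
        want = np.tile((H_j @ W_V).mean(axis=0), (3, 1))
        np.testing.assert_allclose(c.data, want, atol=1e-12)

    def test_zero_value_projection_gives_zero(self):
        H = RNG.standard_normal((2, 4))
        c = cross_modal_attention(H, H + 1, RNG.standard_normal((4, 4)),
                                  RNG.standard_normal((4, 4)),
                                  np.zeros((4, 4)), d_k=4)
        np.testing.assert_array_equal(c.data, 0.0)

    def test_one_token_toy_matches_explicit_arithmetic(self):
        H_i = np.array([[1.0, 2.0]])
        H_j = np.array([[0.5, -1.0]])
        W_Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        W_K = np.array([[0.0, 1.0], [1.0, 0.0]])
        W_V = np.array([[2.0, 0.0], [0.0, 3.0]])
        c = cross_modal_attention(H_i, H_j, W_Q, W_K, W_V, d_k=2)
        # one key: softmax weight is exactly 1, so C = H_j W_V
        np.testing.assert_allclose(c.data, [[1.0, -3.0]], atol=1e-12)

    def test_multi_token_weights_match_loop(self):
        H_i = RNG.standard_normal((3, 4))
        H_j = RNG.standard_normal((4, 4))
        Ws = [RNG.standard_normal((4, 4)) for _ in range(3)]
        out, w = cross_modal_attention(H_i, H_j, *Ws, d_k=4, return_weights=True)
        q, k, v = H_i @ Ws[0], H_j @ Ws[1], H_j @ Ws[2]
        want = np.empty((3, 4))
        for i in range(3):
            s = np.array([q[i] @ k[j] / 2.0 for j in range(4)])
            e = np.exp(s - s.max())
            a = e / e.sum()
            want[i] = sum(a[j] * v[j] for j in range(4))
        np.testing.assert_allclose(out.data, want, atol=1e-6)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


class TestFusion:
    def test_single_modality_fusion_is_identity(self):
        m = _model(dims=(3,), h=4, heads=2)
        H = Tensor(RNG.standard_normal((2, 1, 4)))
        np.testing.assert_array_equal(m.fuse(H).data, H.data)

    def test_zero_cross_values_leave_tokens_unchanged(self):
        m = _model(dims=(3, 2), h=4, heads=2)
        m.params["cross_Wv"].data[:] = 0.0
        H = Tensor(RNG.standard_normal((2, 2, 4)))
        np.testing.assert_allclose(m.fuse(H).data, H.data, atol=1e-12)

    def test_two_modality_fusion_adds_cross_terms_rowwise(self):
        m = _model(dims=(3, 2), h=4, heads=2)
        H = Tensor(RNG.standard_normal((2, 2, 4)))
        got = m.fuse(H).data
        p = m.params
        for s in range(2):
            for i, j in ((0, 1), (1, 0)):
                c = cross_modal_attention(H.data[s, i:i + 1], H.data[s, j:j + 1],
                                          p["cross_Wq"].data, p["cross_Wk"].data,
                                          p["cross_Wv"].data, m.config.key_dim)
                np.testing.assert_allclose(
                    got[s, i], H.data[s, i] + c.data[0], atol=1e-9)

    def test_fusion_off_blocks_cross_modality_information(self):
        """With diagonal attention and no cross terms, modality 2's input
        cannot influence modality 1's fused token."""
        m = _model(dims=(3, 2), h=4, heads=2)
        x1 = RNG.standard_normal((4, 3))
        base = m.fused_representation([x1, np.zeros((4, 2))], fusion=False)
        pert = m.fused_representation([x1, RNG.standard_normal((4, 2))],
                                      fusion=False)
        np.testing.assert_allclose(base.H_fused[:, 0, :], pert.H_fused[:, 0, :],
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# classification head and prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def test_uniform_logits_tie_breaks_to_lowest_class(self):
        p, yhat = predict(np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(p, [[0.5, 0.5]])
        assert yhat[0] == 0

    def test_closed_form_softmax(self):
        p, _ = predict(np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(p, [[0.73105858, 0.26894142]], atol=1e-8)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(z=arrays(float, (4, 3), elements=st.floats(-30, 30)),
           c=st.floats(-50, 50))
    def test_shift_invariance_and_normalisation(self, z, c):
        p1, y1 = predict(z)
        p2, y2 = predict(z + c)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-9)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax_probs(np.array([[np.inf, 0.0]]))


def test_modality_permutation_equivariance_with_tied_parameters():
    """Swapping modality order together with the manifest (and re-indexing the
    modality-specific parameters) leaves the pooled representation unchanged."""
    cfg = EncoderConfig(modality_dims=(3, 3), n_classes=2, embed_dim=4,
                        n_layers=1, n_heads=2, dropout_rate=0.0, seed=21)
    m = CrossModalEncoder(cfg)
    # tie the positional encoding rows so the token slots are exchangeable
    m.params["pos"].data[1] = m.params["pos"].data[0]
    x1, x2 = RNG.standard_normal((5, 3)), RNG.standard_normal((5, 3))
    pooled_a = m.fused_representation([x1, x2]).pooled
    swapped = CrossModalEncoder(cfg, dict(m.params))
    swapped.params = dict(m.params)
    swapped.params["emb0_W"], swapped.params["emb1_W"] = \
        m.params["emb1_W"], m.params["emb0_W"]
    swapped.params["emb0_b"], swapped.params["emb1_b"] = \
        m.params["emb1_b"], m.params["emb0_b"]
    pooled_b = swapped.fused_representation([x2, x1]).pooled
    np.testing.assert_allclose(pooled_a, pooled_b, atol=1e-9)
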