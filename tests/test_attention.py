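"""Self-attention encoder: positional encoding, attention, FFN, layers."""

import numpy as np
import pytest

from medwsd.attention import (
    AttentionEncoder,
    AttentionParams,
    EncoderLayerParams,
    FFNParams,
    attention_weights,
    encode_attention,
    encoder_layer,
    multi_head_attention,
    positional_encoding,
    positionwise_ffn,
    scaled_dot_product_attention,
)


def loop_attention_oracle(Q, K, V):
    """Per-position softmax-weighted sum, written as explicit loops."""
    T, d_k = Q.shape
    out = np.zeros((T, V.shape[1]))
    for a in range(T):
        p = np.array([Q[a] @ K[t] for t in range(T)]) / np.sqrt(d_k)
        s = np.exp(p - p.max())
        s /= s.sum()
        for t in range(T):
            out[a] += s[t] * V[t]
    return out


class TestPositionalEncoding:
    def test_first_row_alternates_zero_one(self):
        pe = positional_encoding(3, 8)
        np.testing.assert_array_equal(pe[0], [0, 1] * 4)

    def test_second_row_first_pair_is_sin1_cos1(self):
        pe = positional_encoding(2, 6)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))
        assert pe[1, 0] == pytest.approx(0.84147, abs=1e-5)

    def test_offset_rows_are_rotations_of_earlier_rows(self):
        d = 12
        pe = positional_encoding(40, d)
        for t in (0, 3, 11):
            for k in (1, 5, 17):
                for i in range(d // 2):
                    theta = k / 10000 ** (2 * i / d)
                    R = np.array(
                        [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
                    )
                    pair_t = pe[t, 2 * i : 2 * i + 2]
                    pair_tk = pe[t + k, 2 * i : 2 * i + 2]
                    np.testing.assert_allclose(pair_tk, R @ pair_t, atol=1e-9)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestScaledDotProductAttention:
    def test_single_position_returns_its_value(self, rng):
        Q = rng.normal(size=(1, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 2))
        np.testing.assert_allclose(scaled_dot_product_attention(Q, K, V), V, atol=1e-12)

    def test_orthogonal_query_averages_values(self, rng):
        K = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Q = np.zeros((3, 2))  # all scores zero -> uniform weights
        V = rng.normal(size=(3, 4))
        out = scaled_dot_product_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (3, 1)), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        Q, K = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        V = rng.normal(size=(3, 2))
        out = scaled_dot_product_attention(Q, K, V)
        np.testing.assert_allclose(out, loop_attention_oracle(Q, K, V), atol=1e-6)

    def test_weights_are_normalized_and_masked_keys_get_exact_zero(self, rng):
        Q, K = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        mask = np.array([True, True, False, True])
        W = attention_weights(Q, K, mask)
        np.testing.assert_allclose(W.sum(axis=1), np.ones(4), atol=1e-6)
        assert np.all(W[:, 2] == 0.0)

    def test_outputs_are_convex_combinations_of_valid_values(self, rng):
        Q, K = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        V = rng.normal(size=(5, 4))
        mask = np.array([True, False, True, True, False])
        out = scaled_dot_product_attention(Q, K, V, mask)
        valid = V[mask]
        assert np.all(out <= valid.max(axis=0) + 1e-12)
        assert np.all(out >= valid.min(axis=0) - 1e-12)

    def test_no_valid_keys_raises(self, rng):
        Q = rng.normal(size=(2, 2))
        with pytest.raises(ValueError):
            scaled_dot_product_attention(Q, Q, Q, np.zeros(2, dtype=bool))

    def test_score_scale_grows_like_sqrt_dk_under_duplication(self, rng):
        """Duplicating Q,K columns doubles raw dot products but the 1/sqrt(d_k)
        scaling keeps the used score only ~sqrt(2) larger."""
        Q, K = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        s1 = (Q @ K.T) / np.sqrt(4)
        Q2, K2 = np.hstack([Q, Q]), np.hstack([K, K])
        s2 = (Q2 @ K2.T) / np.sqrt(8)
        ratio = np.abs(s2).max() / np.abs(s1).max()
        assert ratio == pytest.approx(np.sqrt(2), abs=1e-9)


class TestMultiHead:
    def test_one_head_identity_projection_reduces_to_sdpa(self, rng):
        d = 4
        p = AttentionParams.init(d, 1, rng)
        p.W_o.data[...] = np.eye(d)
        X = rng.normal(size=(3, d))
        expected = scaled_dot_product_attention(
            X @ p.W_q[0].data, X @ p.W_k[0].data, X @ p.W_v[0].data
        )
        np.testing.assert_allclose(multi_head_attention(X, p), expected, atol=1e-12)

    def test_output_shape_is_input_shape(self, rng):
        p = AttentionParams.init(8, 4, rng)
        X = rng.normal(size=(5, 8))
        assert multi_head_attention(X, p).shape == (5, 8)

    def test_two_heads_match_sequential_oracle(self, rng):
        d, h = 8, 2
        p = AttentionParams.init(d, h, rng)
        X = rng.normal(size=(5, d))
        heads = [
            loop_attention_oracle(X @ p.W_q[i].data, X @ p.W_k[i].data, X @ p.W_v[i].data)
            for i in range(h)
        ]
        expected = np.hstack(heads) @ p.W_o.data
        np.testing.assert_allclose(multi_head_attention(X, p), expected, atol=1e-6)

    def test_head_count_must_divide_d_model(self, rng):
        with pytest.raises(ValueError):
            AttentionParams.init(10, 3, rng)


class TestFFN:
    def test_identity_weights_pass_nonnegative_input(self, rng):
        d = 4
        p = FFNParams.init(d, rng)
        p.W_1.data[...] = np.eye(d)
        p.W_2.data[...] = np.eye(d)
        p.b_1.data[...] = 0
        p.b_2.data[...] = 0
        Z = np.abs(rng.normal(size=(3, d)))
        np.testing.assert_allclose(positionwise_ffn(Z, p), Z, atol=1e-12)

    def test_negative_preactivation_yields_bias_only(self, rng):
        d = 3
        p = FFNParams.init(d, rng)
        p.b_1.data[...] = -100.0
        p.b_2.data[...] = 0.25
        Z = rng.normal(size=(4, d))
        np.testing.assert_allclose(positionwise_ffn(Z, p), np.full((4, d), 0.25))

    def test_position_permutation_equivariance(self, rng):
        p = FFNParams.init(4, rng)
        Z = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            positionwise_ffn(Z, p)[perm], positionwise_ffn(Z[perm], p), atol=1e-12
        )


class TestEncoderLayer:
    def test_rows_are_standardized_with_unit_gain_zero_bias(self, rng):
        p = EncoderLayerParams.init(6, 2, rng)
        X = rng.normal(size=(4, 6))
        out = encoder_layer(X, p)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-4)

    def test_masked_rows_do_not_influence_valid_rows(self, rng):
        p = EncoderLayerParams.init(4, 2, rng)
        X = rng.normal(size=(5, 4))
        mask = np.array([True, True, True, False, False])
        base = encoder_layer(X, p, mask)
        X2 = X.copy()
        X2[3:] = rng.normal(size=(2, 4)) * 50
        altered = encoder_layer(X2, p, mask)
        np.testing.assert_allclose(altered[:3], base[:3], atol=1e-12)


class TestEncodeAttention:
    def test_output_shapes_match_d_model(self, rng):
        enc = AttentionEncoder(8, n_heads=2, rng=rng)
        X = rng.normal(size=(5, 8))
        out = encode_attention(X, np.ones(5, dtype=bool), enc)
        assert out.Y.shape == out.Z.shape == (5, 8)

    def test_without_pe_encoder_is_permutation_equivariant(self, rng):
        enc = AttentionEncoder(6, n_heads=2, use_pe=False, rng=rng)
        X = rng.normal(size=(5, 6))
        mask = np.ones(5, dtype=bool)
        perm = rng.permutation(5)
        out = encode_attention(X, mask, enc)
        out_p = encode_attention(X[perm], mask, enc)
        np.testing.assert_allclose(out_p.Z, out.Z[perm], atol=1e-10)
        np.testing.assert_allclose(out_p.Y, out.Y[perm], atol=1e-10)

    def test_with_pe_permutation_changes_more_than_row_order(self, rng):
        enc = AttentionEncoder(6, n_heads=2, use_pe=True, rng=rng)
        X = rng.normal(size=(5, 6))
        mask = np.ones(5, dtype=bool)
        perm = np.array([4, 2, 0, 1, 3])
        out = encode_attention(X, mask, enc)
        out_p = encode_attention(X[perm], mask, enc)
        assert np.abs(out_p.Z - out.Z[perm]).max() > 1e-3

    def test_masked_rows_are_zero(self, rng):
        enc = AttentionEncoder(4, n_heads=2, rng=rng)
        X = rng.normal(size=(6, 4))
        mask = np.array([True] * 4 + [False] * 2)
        out = encode_attention(X, mask, enc)
        np.testing.assert_allclose(out.Y[4:], 0.0)
        np.testing.assert_allclose(out.Z[4:], 0.0)
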