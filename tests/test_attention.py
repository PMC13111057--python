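import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bcstgcn.attention import (AttentionParams, attention_normalize,
                               attention_scores, bc_spatial_conv,
                               compute_attention_maps, local_attention,
                               plain_spatial_conv, threshold_global)
from bcstgcn.skeleton import KeypointScheme, build_adjacency


def make_params(F, Fp, rng=None, **kw):
    rng = rng or np.random.default_rng(0)
    return AttentionParams(W=rng.normal(size=(F, Fp)),
                           a=rng.normal(size=(2 * Fp,)), **kw)


class TestScores:
    def test_zero_scoring_vector_gives_zero_matrix(self):
        p = AttentionParams(W=np.ones((2, 3)), a=np.zeros(6))
        e = attention_scores(np.random.default_rng(1).normal(size=(5, 2)), p)
        assert np.array_equal(e, np.zeros((5, 5)))

    def test_identical_node_features_give_constant_matrix(self):
        p = make_params(3, 2)
        h = np.tile([1.0, -2.0, 0.5], (6, 1))
        e = attention_scores(h, p)
        assert np.allclose(e, e[0, 0])

    def test_hand_evaluated_two_node_case(self):
        # W=[1], a=[1,1], h=[[1],[2]]: e_kl = Wh_k + Wh_l, all positive
        p = AttentionParams(W=np.array([[1.0]]), a=np.array([1.0, 1.0]),
                            leaky_slope=0.2)
        e = attention_scores(np.array([[1.0], [2.0]]), p)
        assert np.allclose(e, [[2.0, 3.0], [3.0, 4.0]])

    def test_leaky_slope_applies_to_negative_scores(self):
        p = AttentionParams(W=np.array([[1.0]]), a=np.array([1.0, 1.0]),
                            leaky_slope=0.2)
        e = attention_scores(np.array([[-1.0], [-2.0]]), p)
        assert np.allclose(e, 0.2 * np.array([[-2.0, -3.0], [-3.0, -4.0]]))

    def test_dimension_mismatch_raises(self):
        p = make_params(3, 2)
        with pytest.raises(ValueError):
            attention_scores(np.zeros((4, 5)), p)


class TestNormalize:
    def test_constant_matrix_becomes_uniform(self):
        alpha = attention_normalize(np.full((7, 7), 3.2))
        assert np.allclose(alpha, 1 / 7)

    def test_dominant_entry_approaches_one_hot(self):
        e = np.zeros((3, 3))
        e[np.arange(3), [2, 0, 1]] = 50.0
        alpha = attention_normalize(e)
        assert np.allclose(alpha[np.arange(3), [2, 0, 1]], 1.0, atol=1e-6)

    def test_closed_form_row(self):
        alpha = attention_normalize(np.array([[0.0, np.log(3.0)]]))
        assert np.allclose(alpha, [[0.25, 0.75]])

    @given(arrays(np.float64, (6, 6), elements=st.floats(-20, 20)))
    @settings(max_examples=50, deadline=None)
    def test_rows_are_stochastic(self, e):
        alpha = attention_normalize(e)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha >= 0).all()


class TestThreshold:
    @pytest.mark.parametrize("C,lam,expected", [
        (np.array([[0.6, 0.4], [0.2, 0.8]]), 0.5,
         np.array([[0.6, 0.0], [0.0, 0.8]])),
        (np.array([[0.1, 0.2]]), 0.9, np.zeros((1, 2))),
        (np.array([[0.3, 0.7]]), 0.0, np.array([[0.3, 0.7]])),
    ])
    def test_known_cases(self, C, lam, expected):
        assert np.array_equal(threshold_global(C, lam), expected)

    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 1)),
           st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, C, lam):
        once = threshold_global(C, lam)
        assert np.array_equal(threshold_global(once, lam), once)

    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 1)),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_sparsity_monotone_in_threshold(self, C, lam1, lam2):
        lo, hi = min(lam1, lam2), max(lam1, lam2)
        assert (np.count_nonzero(threshold_global(C, hi))
                <= np.count_nonzero(threshold_global(C, lo)))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_global(np.ones((2, 2)), -0.1)


class TestLocalAttention:
    def test_full_mask_returns_alpha(self):
        alpha = attention_normalize(np.random.default_rng(2).normal(size=(4, 4)))
        assert np.allclose(local_attention(alpha, np.ones((4, 4))), alpha)

    def test_zero_mask_returns_zero(self):
        alpha = np.full((3, 3), 1 / 3)
        assert np.array_equal(local_attention(alpha, np.zeros((3, 3))),
                              np.zeros((3, 3)))

    def test_two_entry_row_renormalizes_to_half(self):
        alpha = np.full((4, 4), 0.25)
        mask = np.zeros((4, 4))
        mask[0, [1, 3]] = 1
        out = local_attention(alpha, mask)
        assert np.allclose(out[0], [0, 0.5, 0, 0.5])
        assert np.array_equal(out[1:], np.zeros((3, 4)))

    def test_mask_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            local_attention(np.ones((3, 3)) / 3, np.ones((2, 2)))


def dense_bc_oracle(f_in, A_norm, B, C, M, W):
    """Brute-force per-frame matrix-product implementation."""
    C_in, T, V = f_in.shape
    C_out = W.shape[1]
    out = np.zeros((C_out, T, V))
    for k in range(A_norm.shape[0]):
        mix = A_norm[k] * B[k] * M[k] + C[k]
        for t in range(T):
            out[:, t, :] += W[k] @ (f_in[:, t, :] @ mix)
    return out


class TestBCSpatialConv:
    @pytest.fixture
    def path3_adj(self):
        scheme = KeypointScheme(names=("a", "b", "c"), edges=((1, 2), (2, 3)))
        return build_adjacency(scheme, "uniform")

    def test_disabled_attention_reduces_to_plain_conv(self, adj):
        rng = np.random.default_rng(3)
        f_in = rng.normal(size=(4, 6, 17))
        M = rng.normal(size=(adj.K, 17, 17))
        W = rng.normal(size=(adj.K, 5, 4))
        ones = np.ones((adj.K, 17, 17))
        zeros = np.zeros((adj.K, 17, 17))
        a = bc_spatial_conv(f_in, adj, B=ones, C=zeros, M=M, W=W)
        b = plain_spatial_conv(f_in, adj, M=M, W=W)
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_input_gives_zero_output(self, adj):
        rng = np.random.default_rng(4)
        out = bc_spatial_conv(np.zeros((2, 3, 17)), adj,
                              B=rng.random((3, 17, 17)),
                              C=rng.random((17, 17)),
                              M=rng.random((3, 17, 17)),
                              W=rng.random((3, 4, 2)))
        assert np.array_equal(out, np.zeros((4, 3, 17)))

    def test_matches_dense_oracle(self, path3_adj):
        rng = np.random.default_rng(5)
        K, V = path3_adj.K, 3
        f_in = rng.normal(size=(2, 4, V))
        B = rng.random((K, V, V))
        C = rng.random((K, V, V))
        M = rng.random((K, V, V))
        W = rng.normal(size=(K, 3, 2))
        out = bc_spatial_conv(f_in, path3_adj, B=B, C=C, M=M, W=W)
        expected = dense_bc_oracle(f_in, path3_adj.A_norm, B, C, M, W)
        assert np.allclose(out, expected, atol=1e-6)

    def test_matches_dense_oracle_full_skeleton(self, adj):
        rng = np.random.default_rng(6)
        K, V = adj.K, adj.V
        f_in = rng.normal(size=(3, 5, V))
        B = rng.random((K, V, V))
        C = rng.random((V, V))
        M = rng.random((K, V, V))
        W = rng.normal(size=(K, 6, 3))
        out = bc_spatial_conv(f_in, adj, B=B, C=C, M=M, W=W)
        expected = dense_bc_oracle(f_in, adj.A_norm,
                                   B, np.broadcast_to(C, (K, V, V)), M, W)
        assert np.allclose(out, expected, atol=1e-6)

    def test_partition_count_mismatch_raises(self, adj):
        with pytest.raises(ValueError):
            bc_spatial_conv(np.zeros((2, 3, 17)), adj,
                            B=np.ones((2, 17, 17)),
                            C=np.zeros((2, 17, 17)),
                            M=np.ones((2, 17, 17)),
                            W=np.ones((2, 4, 2)))


class TestAttentionMaps:
    def test_local_support_respects_partitions(self, adj):
        rng = np.random.default_rng(7)
        h = rng.normal(size=(17, 4))
        maps = compute_attention_maps(h, make_params(4, 3, rng, C_lambda=0.05),
                                      adj)
        for k in range(adj.K):
            outside = maps.B[k] * (adj.A[k] == 0)
            assert np.array_equal(outside, np.zeros((17, 17)))
        assert np.allclose(maps.alpha.sum(axis=1), 1.0, atol=1e-6)
        nz = maps.C[maps.C != 0]
        assert (nz > 0.05).all()
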