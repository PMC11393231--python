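"""Dual-self-attention: oracle equivalence, shapes, and scaling laws.

The dense oracles below are written as straight-line NumPy translations
of the attention equations, independent of the package's batched,
multi-head implementation path.
"""

import numpy as np
import pytest

from dsaseg import (AttentionConfig, AttentionProjections, ConfigError,
                    DSAModule, NetworkConfig, Pathway, ShapeError,
                    TokenSequence, channel_self_attention, detokenize,
                    dsa_forward, pathway_forward, spatial_self_attention,
                    tokenize)
from dsaseg.autodiff import Tensor, count_multiplies


def softmax_rows(a):
    e = np.exp(a - a.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def dense_ssa_oracle(Q, K_bar, Vs_bar, s):
    """Straight-line spatial attention: softmax(Q K_bar^T / sqrt(s)) V_bar."""
    A = softmax_rows(Q @ K_bar.T / np.sqrt(s))
    return A @ Vs_bar, A


def dense_csa_oracle(Q, K, Vc, s):
    """Straight-line channel attention: Vc softmax(Q^T K / sqrt(s))."""
    A = softmax_rows(Q.T @ K / np.sqrt(s))
    return Vc @ A, A


class TestTokenize:
    def test_token_count_is_product_of_spatial_extents(self, rng):
        fm = rng.normal(size=(8, 4, 4, 4))
        ts = tokenize(fm)
        assert ts.tokens.shape == (64, 8)
        assert ts.origin_shape == (4, 4, 4)

    def test_zero_embedding_equals_layer_normalised_flattening(self, rng):
        fm = rng.normal(size=(3, 2, 2, 2))
        with_zero = tokenize(fm, e=np.zeros((8, 3)))
        without = tokenize(fm)
        np.testing.assert_allclose(with_zero.tokens, without.tokens)
        flat = fm.reshape(3, 8).T
        mu, sd = flat.mean(1, keepdims=True), flat.std(1, keepdims=True)
        np.testing.assert_allclose(without.tokens, (flat - mu) / np.sqrt(sd ** 2 + 1e-5),
                                   atol=1e-6)

    def test_round_trip_recovers_layer_normalised_map(self, rng):
        """detokenize inverts the flatten/transpose exactly (index oracle)."""
        fm = rng.normal(size=(2, 2, 3, 4))
        ts = tokenize(fm, e=np.zeros((24, 2)))
        back = detokenize(ts.tokens, ts.origin_shape)
        # independent index bookkeeping: token t = (d*h_ext + h)*w_ext + w
        for d in range(2):
            for h in range(3):
                for w in range(4):
                    t = (d * 3 + h) * 4 + w
                    np.testing.assert_array_equal(back[:, d, h, w], ts.tokens[t])

    def test_embedding_shape_mismatch_raises(self, rng):
        with pytest.raises(ShapeError, match="embedding"):
            tokenize(rng.normal(size=(2, 2, 2, 2)), e=np.zeros((9, 2)))


class TestSpatialSelfAttention:
    def test_rows_of_attention_map_sum_to_one(self, rng):
        cfg = AttentionConfig(heads=2, proj_dim=4)
        proj = AttentionProjections(Q=rng.normal(size=(16, 8)),
                                    K=rng.normal(size=(16, 8)),
                                    K_bar=rng.normal(size=(4, 8)),
                                    Vs_bar=rng.normal(size=(4, 8)))
        _, attn = spatial_self_attention(proj, cfg, return_attention=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_small_explicit_case_matches_dense_oracle(self):
        cfg = AttentionConfig(heads=1, proj_dim=2)
        Q = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, -0.5]])
        K_bar = np.array([[1.0, 2.0], [-1.0, 0.5]])
        Vs_bar = np.array([[0.0, 1.0], [1.0, 0.0]])
        proj = AttentionProjections(Q=Q, K=Q, K_bar=K_bar, Vs_bar=Vs_bar)
        x_s = spatial_self_attention(proj, cfg)
        expected, _ = dense_ssa_oracle(Q, K_bar, Vs_bar, s=2.0)
        np.testing.assert_allclose(x_s, expected, atol=1e-6)

    def test_shapes_follow_projection_dimension(self, rng):
        cfg = AttentionConfig(heads=1, proj_dim=16)
        proj = AttentionProjections(Q=rng.normal(size=(64, 8)),
                                    K=rng.normal(size=(64, 8)),
                                    K_bar=rng.normal(size=(16, 8)),
                                    Vs_bar=rng.normal(size=(16, 8)))
        x_s, attn = spatial_self_attention(proj, cfg, return_attention=True)
        assert attn.shape == (64, 16)
        assert x_s.shape == (64, 8)

    def test_multi_head_matches_per_head_dense_oracle(self, rng):
        n, c, p, n_h = 12, 8, 4, 2
        Q, K = rng.normal(size=(n, c)), rng.normal(size=(n, c))
        K_bar, Vs_bar = rng.normal(size=(p, c)), rng.normal(size=(p, c))
        cfg = AttentionConfig(heads=n_h, proj_dim=p)
        x_s = spatial_self_attention(
            AttentionProjections(Q=Q, K=K, K_bar=K_bar, Vs_bar=Vs_bar), cfg)
        ch = c // n_h
        s = c / n_h
        parts = [dense_ssa_oracle(Q[:, i*ch:(i+1)*ch], K_bar[:, i*ch:(i+1)*ch],
                                  Vs_bar[:, i*ch:(i+1)*ch], s)[0]
                 for i in range(n_h)]
        np.testing.assert_allclose(x_s, np.concatenate(parts, axis=1), atol=1e-6)

    def test_identity_projection_with_p_equal_n_is_full_attention(self, rng):
        """With K_bar = K and Vs_bar = Vs the projected SSA must coincide
        with dense unprojected attention."""
        n, c = 64, 8
        Q, K, Vs = (rng.normal(size=(n, c)) for _ in range(3))
        cfg = AttentionConfig(heads=1, proj_dim=n)
        x_s = spatial_self_attention(
            AttentionProjections(Q=Q, K=K, K_bar=K, Vs_bar=Vs), cfg)
        dense, A = dense_ssa_oracle(Q, K, Vs, s=float(c))
        assert A.shape == (n, n)
        np.testing.assert_allclose(x_s, dense, atol=1e-5)

    def test_projection_larger_than_sequence_is_rejected(self, rng):
        cfg = AttentionConfig(heads=1, proj_dim=8)
        proj = AttentionProjections(Q=rng.normal(size=(4, 2)),
                                    K=rng.normal(size=(4, 2)),
                                    K_bar=rng.normal(size=(8, 2)),
                                    Vs_bar=rng.normal(size=(8, 2)))
        with pytest.raises(ConfigError, match="exceeds"):
            spatial_self_attention(proj, cfg)

    def test_heads_must_divide_channels(self, rng):
        cfg = AttentionConfig(heads=3, proj_dim=2)
        proj = AttentionProjections(Q=rng.normal(size=(4, 4)),
                                    K=rng.normal(size=(4, 4)),
                                    K_bar=rng.normal(size=(2, 4)),
                                    Vs_bar=rng.normal(size=(2, 4)))
        with pytest.raises(ConfigError, match="divide"):
            spatial_self_attention(proj, cfg)

    def test_multiply_count_scales_linearly_in_sequence_length(self, rng):
        """Projected attention work is O(n*p): quadrupling n at fixed p
        must quadruple (not 16x) the multiply count."""
        cfg = AttentionConfig(heads=1, proj_dim=8)
        counts = {}
        for n in (64, 256):
            proj = AttentionProjections(Q=rng.normal(size=(n, 8)),
                                        K=rng.normal(size=(n, 8)),
                                        K_bar=rng.normal(size=(8, 8)),
                                        Vs_bar=rng.normal(size=(8, 8)))
            with count_multiplies() as counter:
                spatial_self_attention(proj, cfg)
            counts[n] = counter.count
        assert counts[256] == 4 * counts[64]

    def test_permuting_tokens_permutes_output_rows(self, rng):
        cfg = AttentionConfig(heads=2, proj_dim=4)
        n, c = 16, 8
        Q, K = rng.normal(size=(n, c)), rng.normal(size=(n, c))
        K_bar, Vs_bar = rng.normal(size=(4, c)), rng.normal(size=(4, c))
        perm = rng.permutation(n)
        base = spatial_self_attention(
            AttentionProjections(Q=Q, K=K, K_bar=K_bar, Vs_bar=Vs_bar), cfg)
        permuted = spatial_self_attention(
            AttentionProjections(Q=Q[perm], K=K, K_bar=K_bar, Vs_bar=Vs_bar), cfg)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-6)


class TestChannelSelfAttention:
    def test_shapes_and_normalisation(self, rng):
        cfg = AttentionConfig(heads=1)
        Q, K, Vc = (rng.normal(size=(64, 8)) for _ in range(3))
        x_c, attn = channel_self_attention(
            AttentionProjections(Q=Q, K=K, Vc=Vc), cfg, return_attention=True)
        assert attn.shape == (8, 8)
        assert x_c.shape == (64, 8)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_small_explicit_case_matches_hand_computation(self):
        cfg = AttentionConfig(heads=1)
        Q = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        K = np.array([[0.2, -0.1], [0.0, 0.3], [1.0, 1.0]])
        Vc = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        x_c = channel_self_attention(AttentionProjections(Q=Q, K=K, Vc=Vc), cfg)
        expected, _ = dense_csa_oracle(Q, K, Vc, s=2.0)
        np.testing.assert_allclose(x_c, expected, atol=1e-6)


class TestDSAModule:
    def test_zeroed_value_projections_leave_tokens_unchanged(self, rng):
        cfg = AttentionConfig(heads=1, proj_dim=4, modules_per_pathway=1)
        mod = DSAModule(4, (2, 2, 2), cfg, rng=np.random.default_rng(3))
        mod.wvs.weight.data[:] = 0
        mod.wvs.bias.data[:] = 0
        mod.wvc.weight.data[:] = 0
        mod.wvc.bias.data[:] = 0
        fm = rng.normal(size=(4, 2, 2, 2)).astype(np.float32)
        ts = tokenize(fm, e=mod.embedding.data, level=None)
        _, pre_tail = dsa_forward(ts, mod, return_pre_tail=True)
        np.testing.assert_allclose(pre_tail, ts.tokens, atol=1e-5)

    @pytest.mark.parametrize("shape", [(4, 2, 2, 2), (8, 2, 4, 2), (4, 4, 4, 4)])
    def test_output_shape_equals_input_shape(self, shape, rng):
        cfg = AttentionConfig(heads=2, proj_dim=4, modules_per_pathway=1)
        mod = DSAModule(shape[0], shape[1:], cfg, rng=np.random.default_rng(0))
        out = mod(Tensor(rng.normal(size=(1,) + shape).astype(np.float32)))
        assert out.shape == (1,) + shape

    def test_tiny_module_matches_scripted_equation_composition(self, rng):
        """End-to-end pre-tail output vs an independently scripted chain:
        embed -> layer-norm -> Q/K/V -> project -> SSA + CSA -> residual."""
        cfg = AttentionConfig(heads=1, proj_dim=2, modules_per_pathway=1)
        mod = DSAModule(4, (2, 2, 2), cfg, rng=np.random.default_rng(8))
        fm = rng.normal(size=(4, 2, 2, 2)).astype(np.float32)

        out, pre_tail = mod(Tensor(fm[None]), return_pre_tail=True)
        pre_tail = pre_tail.data[0]

        # independent straight-line script
        x = fm.reshape(4, 8).T + mod.embedding.data
        mu, var = x.mean(1, keepdims=True), x.var(1, keepdims=True)
        t = (x - mu) / np.sqrt(var + 1e-5)
        t = t * mod.ln.gain.data + mod.ln.bias.data
        Q = t @ mod.wq.weight.data + mod.wq.bias.data
        K = t @ mod.wk.weight.data + mod.wk.bias.data
        Vs = t @ mod.wvs.weight.data + mod.wvs.bias.data
        Vc = t @ mod.wvc.weight.data + mod.wvc.bias.data
        K_bar = mod.proj_k.data @ K
        Vs_bar = mod.proj_vs.data @ Vs
        s = 4.0  # c / n_h
        x_s = softmax_rows(Q @ K_bar.T / np.sqrt(s)) @ Vs_bar
        x_c = Vc @ softmax_rows(Q.T @ K / np.sqrt(s))
        z_expected = t + x_s + x_c
        np.testing.assert_allclose(pre_tail, z_expected, atol=1e-5)

        # and the tail preserves the feature-map shape
        assert out.shape == (1, 4, 2, 2, 2)


class TestPathway:
    def test_default_pathway_applies_three_dsa_modules(self, rng):
        cfg = AttentionConfig(heads=1, proj_dim=4, modules_per_pathway=3)
        pw = Pathway(8, (2, 2, 2), cfg, rng=np.random.default_rng(0))
        assert len(pw.dsa_modules) == 3
        pw(Tensor(rng.normal(size=(1, 8, 2, 2, 2)).astype(np.float32)))
        assert [m.call_count for m in pw.dsa_modules] == [1, 1, 1]

    def test_single_module_pathway_degenerates_to_one_dsa(self, rng):
        cfg = AttentionConfig(heads=1, proj_dim=4, modules_per_pathway=1)
        pw = Pathway(8, (2, 2, 2), cfg, rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 2, 2, 2)).astype(np.float32))
        out = pw(x)
        manual = pw.dsa_modules[0](pw.pre(x))
        np.testing.assert_allclose(out.data, manual.data, atol=1e-6)
        assert pw.dsa_modules[0].call_count == 2

    def test_level_six_geometry_after_channel_halving(self):
        """A level-6 map of a 128^3 input (512 channels, 4^3 space) tokens
        to n = 64 after halving to 256 channels."""
        cfg = AttentionConfig(heads=8, proj_dim=64, modules_per_pathway=1)
        pw = Pathway(512, (4, 4, 4), cfg, rng=np.random.default_rng(0))
        assert pw.out_channels == 256
        assert pw.dsa_modules[0].n == 64
        assert pw.dsa_modules[0].p == 64

    def test_output_shape_is_channel_halved_input(self, rng):
        cfg = AttentionConfig(heads=2, proj_dim=8, modules_per_pathway=2)
        out = pathway_forward(rng.normal(size=(8, 2, 2, 2)).astype(np.float32),
                              cfg, level=3, seed=4)
        assert out.shape == (4, 2, 2, 2)

    def test_level_without_pathway_is_rejected(self, rng):
        cfg = AttentionConfig()
        with pytest.raises(ConfigError, match="no configured pathway"):
            pathway_forward(rng.normal(size=(8, 2, 2, 2)), cfg, level=2)
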