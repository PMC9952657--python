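"""Cross-shaped-window attention primitives against independent oracles."""

import numpy as np
import pytest

from ctsnet.cswin import (CSWinAttention, CSWinBlock, ConvEmbed, PatchExpand,
                          PatchMerge, conv_embed, h_attention)
from ctsnet.nn import LayerNorm
from ctsnet.tensor import Tensor


def dense_attention(x_flat, wq, wk, wv):
    """Naive O(n^2) scaled dot-product attention over a flat token list."""
    dk = wq.shape[1]
    q, k, v = x_flat @ wq, x_flat @ wk, x_flat @ wv
    logits = q @ k.T / np.sqrt(dk)
    a = np.exp(logits - logits.max(axis=-1, keepdims=True))
    a /= a.sum(axis=-1, keepdims=True)
    return a @ v


class TestConvEmbed:
    def test_stride_four_grid(self, rng):
        emb = ConvEmbed(1, 8, rng, stride=4)
        out = emb(Tensor(rng.random((2, 256, 256, 1))))
        assert out.shape == (2, 64, 64, 8)

    def test_stride_one_preserves_grid(self, rng):
        emb = ConvEmbed(4, 4, rng, stride=1)
        out = emb(Tensor(rng.random((1, 16, 16, 4))))
        assert out.shape == (1, 16, 16, 4)

    def test_zero_input_yields_bias(self, rng):
        w = Tensor(rng.normal(size=(7, 7, 1, 3)))
        b = Tensor(np.array([1.0, -2.0, 0.5]))
        out = conv_embed(Tensor(np.zeros((1, 8, 8, 1))), w, b, stride=4)
        assert np.allclose(out.data, b.data)


class TestStripeAttention:
    def test_full_stripe_equals_dense_oracle(self, rng):
        x = rng.random((1, 6, 6, 8))
        wq, wk, wv = (Tensor(rng.normal(0, 0.3, (8, 4))) for _ in range(3))
        out = h_attention(Tensor(x), wq, wk, wv, sw=6).data
        oracle = dense_attention(x.reshape(36, 8), wq.data, wk.data, wv.data)
        assert np.abs(out.reshape(36, 4) - oracle).max() < 1e-10

    def test_singleton_token_returns_value_projection(self, rng):
        x = rng.random((1, 1, 1, 8))
        wq, wk, wv = (Tensor(rng.normal(size=(8, 4))) for _ in range(3))
        out = h_attention(Tensor(x), wq, wk, wv, sw=1).data
        assert np.allclose(out, x.reshape(1, 8) @ wv.data)

    def test_stripe_permutation_equivariance(self, rng):
        x = rng.random((1, 6, 4, 8))
        wq, wk, wv = (Tensor(rng.normal(size=(8, 4))) for _ in range(3))
        out = h_attention(Tensor(x), wq, wk, wv, sw=2).data
        perm = [4, 5, 0, 1, 2, 3]  # permute whole stripes of 2 rows
        out_p = h_attention(Tensor(x[:, perm]), wq, wk, wv, sw=2).data
        assert np.allclose(out[:, perm], out_p)

    def test_padded_rows_do_not_change_valid_output(self, rng):
        """A grid whose height is not a stripe multiple gives the same
        result as computing each full stripe separately."""
        x = rng.random((1, 5, 3, 8))
        wq, wk, wv = (Tensor(rng.normal(size=(8, 4))) for _ in range(3))
        out = h_attention(Tensor(x), wq, wk, wv, sw=2).data
        for rows in ((0, 2), (2, 4), (4, 5)):
            stripe = x[:, rows[0]:rows[1]]
            flat = stripe.reshape(-1, 8)
            oracle = dense_attention(flat, wq.data, wk.data, wv.data)
            assert np.allclose(out[:, rows[0]:rows[1]].reshape(-1, 4), oracle)


class TestCSWinAttention:
    def test_shape_preserved(self, rng):
        attn = CSWinAttention(8, 4, sw=2, rng=rng)
        out = attn(Tensor(rng.random((2, 8, 4, 8))))
        assert out.shape == (2, 8, 4, 8)

    def test_two_heads_split_into_h_and_v_blocks(self, rng):
        attn = CSWinAttention(8, 2, sw=2, rng=rng, use_lepe=False)
        attn.proj.weight.data = np.eye(8)
        attn.proj.bias.data[:] = 0
        x = rng.random((1, 4, 4, 8))
        out = attn(Tensor(x)).data
        h_part = h_attention(Tensor(x), attn.wq[0], attn.wk[0], attn.wv[0], 2).data
        xt = Tensor(np.swapaxes(x, 1, 2))
        v_part = np.swapaxes(
            h_attention(xt, attn.wq[1], attn.wk[1], attn.wv[1], 2).data, 1, 2)
        assert np.allclose(out[..., :4], h_part)
        assert np.allclose(out[..., 4:], v_part)

    def test_transpose_swaps_branch_roles_with_tied_weights(self, rng):
        attn = CSWinAttention(8, 2, sw=2, rng=rng, use_lepe=False)
        for mats in (attn.wq, attn.wk, attn.wv):
            mats[1].data = mats[0].data.copy()
        attn.proj.weight.data = np.eye(8)
        attn.proj.bias.data[:] = 0
        x = rng.random((1, 4, 4, 8))
        out = attn(Tensor(x)).data
        out_t = attn(Tensor(np.swapaxes(x, 1, 2))).data
        assert np.allclose(np.swapaxes(out_t[..., 4:], 1, 2), out[..., :4])
        assert np.allclose(np.swapaxes(out_t[..., :4], 1, 2), out[..., 4:])

    def test_odd_head_count_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            CSWinAttention(9, 3, sw=1, rng=rng)


class TestBlock:
    def test_zeroed_branch_outputs_make_identity(self, rng):
        blk = CSWinBlock(8, 2, 2, rng)
        blk.attn.proj.weight.data[:] = 0
        blk.attn.proj.bias.data[:] = 0
        blk.mlp.fc2.weight.data[:] = 0
        blk.mlp.fc2.bias.data[:] = 0
        x = rng.random((1, 4, 4, 8))
        assert np.allclose(blk(Tensor(x)).data, x)

    def test_matches_hand_composed_oracle(self, rng):
        blk = CSWinBlock(4, 2, 2, rng)
        x = rng.random((1, 2, 2, 4))

        def ln(v, norm):
            mu = v.mean(-1, keepdims=True)
            var = ((v - mu) ** 2).mean(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + norm.eps) * norm.gamma.data + norm.beta.data

        def erf_gelu(v):
            from scipy.special import erf
            return 0.5 * v * (1 + erf(v / np.sqrt(2)))

        a_in = ln(x, blk.norm1)
        heads = []
        for k in range(2):
            src = a_in if k == 0 else np.swapaxes(a_in, 1, 2)
            flat = src.reshape(4, 4)
            att = dense_attention(flat, blk.attn.wq[k].data, blk.attn.wk[k].data,
                                  blk.attn.wv[k].data).reshape(1, 2, 2, 2)
            # add the depthwise positional term on V
            v = (flat @ blk.attn.wv[k].data).reshape(1, 2, 2, 2)
            vp = np.pad(v, ((0, 0), (1, 1), (1, 1), (0, 0)))
            lepe = sum(vp[:, di:di + 2, dj:dj + 2] * blk.attn.lepe[k].data[di, dj]
                       for di in range(3) for dj in range(3))
            att = att + lepe
            heads.append(att if k == 0 else np.swapaxes(att, 1, 2))
        attn_out = np.concatenate(heads, -1) @ blk.attn.proj.weight.data \
            + blk.attn.proj.bias.data
        xh = attn_out + x
        m_in = ln(xh, blk.norm2)
        hidden = erf_gelu(m_in @ blk.mlp.fc1.weight.data + blk.mlp.fc1.bias.data)
        oracle = hidden @ blk.mlp.fc2.weight.data + blk.mlp.fc2.bias.data + xh
        assert np.abs(blk(Tensor(x)).data - oracle).max() < 1e-6


class TestMergeExpand:
    def test_merge_halves_grid_doubles_channels(self, rng):
        pm = PatchMerge(8, rng)
        out = pm(Tensor(rng.random((1, 8, 8, 8))))
        assert out.shape == (1, 4, 4, 16)

    def test_merge_gather_index_map(self, rng):
        x = rng.random((1, 4, 4, 2))
        g = PatchMerge.gather(Tensor(x)).data
        # documented order: top-left, bottom-left, top-right, bottom-right
        assert np.allclose(g[0, 1, 0, :2], x[0, 2, 0])
        assert np.allclose(g[0, 1, 0, 2:4], x[0, 3, 0])
        assert np.allclose(g[0, 1, 0, 4:6], x[0, 2, 1])
        assert np.allclose(g[0, 1, 0, 6:8], x[0, 3, 1])

    def test_merge_odd_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            PatchMerge.gather(Tensor(rng.random((1, 5, 4, 2))))

    def test_expand_doubles_grid_halves_channels(self, rng):
        pe = PatchExpand(16, rng)
        out = pe(Tensor(rng.random((1, 4, 4, 16))))
        assert out.shape == (1, 8, 8, 8)

    def test_expand_then_merge_preserves_token_count_and_channels(self, rng):
        x = Tensor(rng.random((1, 4, 4, 16)))
        y = PatchMerge(8, rng)(PatchExpand(16, rng)(x))
        assert y.shape == x.shape
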