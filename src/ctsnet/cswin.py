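"""Cross-shaped-window (CSWin) transformer primitives.

Token grids keep their 2-D layout ``(B, H, W, C)``.  Self-attention is
computed inside horizontal stripes of ``sw`` rows (or, for the vertical
branch, stripes of ``sw`` columns via a transpose): half of the heads
attend horizontally, half vertically, and their concatenated outputs are
projected by ``W_O``.  A block (CTB) is the standard pre-norm residual
composition

    X_hat = CSWinAttention(LN(X)) + X
    X_out = MLP(LN(X_hat)) + X_hat

Patch merging halves each spatial side and doubles channels; patch
expanding does the reverse.  If a grid side is not divisible by ``sw``,
tokens are zero-padded to the next multiple, the padded keys are masked
out of the softmax, and the output is cropped back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import LayerNorm, Linear, Mlp, Module
from .tensor import Tensor, concatenate, softmax

__all__ = [
    "BlockSpec",
    "conv_embed",
    "ConvEmbed",
    "h_attention",
    "CSWinAttention",
    "CSWinBlock",
    "PatchMerge",
    "PatchExpand",
    "FinalPatchExpand",
]

_NEG_INF = -1e9


@dataclass
class BlockSpec:
    """Per-block hyperparameters: MLP expansion ratio, LayerNorm epsilon,
    and whether the locally-enhanced positional encoding (a depthwise
    3x3 convolution on V) is added to each head's output."""

    mlp_ratio: float = 4.0
    norm_eps: float = 1e-5
    use_lepe: bool = True

    def __post_init__(self):
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")


# --------------------------------------------------------------------- embed

def conv_embed(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int) -> Tensor:
    """Overlapping convolutional embedding (channel-last, 'same'-style).

    ``x``: (B, H, W, C_in); ``weight``: (k, k, C_in, C_out).  Padding is
    (k-1)//2 on each side, so the output grid is ceil(H/stride) x
    ceil(W/stride).  Implemented as a sum of strided slices times the
    kernel taps, which keeps the backward pass inside the autodiff core.
    """
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    k = weight.shape[0]
    pad = (k - 1) // 2
    b, h, w, _ = x.shape
    ho = -(-h // stride)
    wo = -(-w // stride)
    xp = x.pad(((0, 0), (pad, pad + k), (pad, pad + k), (0, 0)))
    out = None
    for di in range(k):
        for dj in range(k):
            sl = xp[:, di:di + stride * (ho - 1) + 1:stride,
                    dj:dj + stride * (wo - 1) + 1:stride, :]
            term = sl @ weight[di, dj]
            out = term if out is None else out + term
    if bias is not None:
        out = out + bias
    return out


class ConvEmbed(Module):
    """7x7 overlapping convolution + LayerNorm turning rasters into tokens."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel: int = 7, stride: int = 4, norm_eps: float = 1e-5):
        fan_in = kernel * kernel * in_channels
        self.weight = Tensor(rng.normal(0.0, math.sqrt(2.0 / fan_in),
                                        size=(kernel, kernel, in_channels, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.norm = LayerNorm(out_channels, eps=norm_eps)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(conv_embed(x, self.weight, self.bias, self.stride))


# ----------------------------------------------------------------- attention

def _depthwise3x3(v: Tensor, weight: Tensor) -> Tensor:
    """Depthwise 3x3 convolution on a (B, H, W, C) grid; weight (3, 3, C)."""
    b, h, w, c = v.shape
    vp = v.pad(((0, 0), (1, 1), (1, 1), (0, 0)))
    out = None
    for di in range(3):
        for dj in range(3):
            term = vp[:, di:di + h, dj:dj + w, :] * weight[di, dj]
            out = term if out is None else out + term
    return out


def h_attention(x: Tensor, wq: Tensor, wk: Tensor, wv: Tensor, sw: int,
                lepe_weight: Tensor | None = None) -> Tensor:
    """Single-head horizontal-stripe attention.

    ``x``: (B, H, W, C) tokens; ``wq/wk/wv``: (C, d_k) projections.  Rows
    are partitioned into H/sw stripes of shape (sw x W); scaled
    dot-product attention (scale 1/sqrt(d_k)) runs over the sw*W tokens of
    each stripe independently, and stripe outputs are re-assembled in
    order.  Non-divisible H is zero-padded and the padded keys masked out.
    Returns (B, H, W, d_k).
    """
    b, h, w, c = x.shape
    dk = wq.shape[1]
    pad_rows = (-h) % sw
    if pad_rows:
        x = x.pad(((0, 0), (0, pad_rows), (0, 0), (0, 0)))
    hp = h + pad_rows
    m = hp // sw
    s = sw * w

    q = (x @ wq).reshape(b, m, s, dk)
    k = (x @ wk).reshape(b, m, s, dk)
    v = (x @ wv).reshape(b, m, s, dk)

    logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
    if pad_rows:
        valid = np.ones((hp, w), dtype=bool)
        valid[h:] = False
        key_bias = np.where(valid.reshape(m, s), 0.0, _NEG_INF)[None, :, None, :]
        logits = logits + key_bias
    attn = softmax(logits, axis=-1)
    out = (attn @ v).reshape(b, hp, w, dk)
    if pad_rows:
        out = out[:, :h]
    if lepe_weight is not None:
        out = out + _depthwise3x3((x @ wv).reshape(b, hp, w, dk)[:, :h] if pad_rows
                                  else v.reshape(b, h, w, dk), lepe_weight)
    return out


class CSWinAttention(Module):
    """K-head cross-shaped attention: heads 1..K/2 horizontal, rest vertical.

    Each head has independent (C, d_k) query/key/value projections with
    d_k = C / K; concatenated head outputs are projected by W_O (C x C).
    """

    def __init__(self, dim: int, n_heads: int, sw: int, rng: np.random.Generator,
                 use_lepe: bool = True):
        if n_heads % 2 != 0:
            raise ValueError(f"head count must be even (half per direction), got {n_heads}")
        if dim % n_heads != 0:
            raise ValueError(f"channels ({dim}) must divide evenly over {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.d_k = dim // n_heads
        self.sw = sw
        std = 0.02
        self.wq = [Tensor(rng.normal(0, std, (dim, self.d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.wk = [Tensor(rng.normal(0, std, (dim, self.d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.wv = [Tensor(rng.normal(0, std, (dim, self.d_k)), requires_grad=True)
                   for _ in range(n_heads)]
        self.lepe = ([Tensor(rng.normal(0, std, (3, 3, self.d_k)), requires_grad=True)
                      for _ in range(n_heads)] if use_lepe else None)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        half = self.n_heads // 2
        outs = []
        xt = x.transpose(0, 2, 1, 3)
        for head in range(self.n_heads):
            lepe = self.lepe[head] if self.lepe is not None else None
            if head < half:
                outs.append(h_attention(x, self.wq[head], self.wk[head], self.wv[head],
                                        self.sw, lepe))
            else:
                y = h_attention(xt, self.wq[head], self.wk[head], self.wv[head],
                                self.sw, lepe)
                outs.append(y.transpose(0, 2, 1, 3))
        return self.proj(concatenate(outs, axis=-1))


def cswin_attention(x: Tensor, attn: CSWinAttention) -> Tensor:
    """Functional alias for :meth:`CSWinAttention.forward`."""
    return attn(x)


class CSWinBlock(Module):
    """CTB: pre-norm cross-shaped attention and MLP, each with a residual."""

    def __init__(self, dim: int, n_heads: int, sw: int, rng: np.random.Generator,
                 spec: BlockSpec | None = None):
        spec = spec or BlockSpec()
        self.norm1 = LayerNorm(dim, eps=spec.norm_eps)
        self.attn = CSWinAttention(dim, n_heads, sw, rng, use_lepe=spec.use_lepe)
        self.norm2 = LayerNorm(dim, eps=spec.norm_eps)
        self.mlp = Mlp(dim, spec.mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.attn(self.norm1(x)) + x
        return self.mlp(self.norm2(x)) + x


def ctb_forward(x: Tensor, block: CSWinBlock) -> Tensor:
    """Functional alias for :meth:`CSWinBlock.forward`."""
    return block(x)


# ------------------------------------------------------------- down/upsample

class PatchMerge(Module):
    """2x spatial downsample: gather each 2x2 neighbourhood's channels in
    the fixed order (top-left, bottom-left, top-right, bottom-right),
    LayerNorm the 4C vector, and linearly map it to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator, norm_eps: float = 1e-5):
        self.norm = LayerNorm(4 * dim, eps=norm_eps)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    @staticmethod
    def gather(x: Tensor) -> Tensor:
        """The pre-linear 4C concatenation (exposed for index-map tests)."""
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"patch merging needs even grid sides, got {h}x{w}")
        parts = [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
                 x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]]
        return concatenate(parts, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        return self.reduce(self.norm(self.gather(x)))


class PatchExpand(Module):
    """2x spatial upsample: linear C -> 2C, then scatter the channel
    quadruples (p1, p2, C/2) into the 2x2 spatial neighbourhood."""

    def __init__(self, dim: int, rng: np.random.Generator, norm_eps: float = 1e-5):
        if dim % 2:
            raise ValueError(f"patch expanding needs an even channel count, got {dim}")
        self.expand = Linear(dim, 2 * dim, rng, bias=False)
        self.norm = LayerNorm(dim // 2, eps=norm_eps)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = self.expand(x)                                  # (B, H, W, 2C)
        y = y.reshape(b, h, w, 2, 2, c // 2)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, c // 2)
        return self.norm(y)


class FinalPatchExpand(Module):
    """4x spatial upsample keeping C channels (linear C -> 16C, scatter 4x4)."""

    def __init__(self, dim: int, rng: np.random.Generator, norm_eps: float = 1e-5):
        self.expand = Linear(dim, 16 * dim, rng, bias=False)
        self.norm = LayerNorm(dim, eps=norm_eps)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        y = self.expand(x).reshape(b, h, w, 4, 4, c)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(b, 4 * h, 4 * w, c)
        return self.norm(y)
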