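"""The U-shaped CSWin segmentation network.

Encoder: convolutional embedding (7x7, stride 4) to an H/4 token grid at
C channels, a stack of CSWin blocks, then twice [patch merge -> CSWin
blocks], reaching H/16 at 4C.  Decoder: patch expand back up, fusing each
encoder skip by channel concatenation -> linear -> two CSWin blocks; an
auxiliary N-class map is emitted after each fusion stage (at H/8 and
H/4), and a final 4x expansion + 1x1 projection produces the full-
resolution N-class logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cswin import (BlockSpec, ConvEmbed, CSWinBlock, FinalPatchExpand,
                    PatchExpand, PatchMerge)
from .nn import Linear, Module
from .tensor import Tensor, concatenate

__all__ = ["NetworkSpec", "PredictionMaps", "CTSNet", "predict_mask"]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    base_channels: C, the embedding width; depths: CSWin blocks per
    encoder stage; dec_depths: blocks per decoder fusion stage; heads and
    stripe_widths: per encoder stage (decoder stages reuse the matching
    resolution's settings); input spatial sides must be divisible by 16
    (stride-4 embedding plus two 2x mergings).
    """

    base_channels: int = 64
    n_classes: int = 6
    in_channels: int = 1
    depths: tuple = (2, 4, 4)
    dec_depths: tuple = (2, 2)
    heads: tuple = (2, 4, 8)
    stripe_widths: tuple = (1, 2, 4)
    mlp_ratio: float = 4.0
    use_lepe: bool = True
    aux_supervision: bool = False

    def __post_init__(self):
        if len(self.depths) != 3 or len(self.heads) != 3 or len(self.stripe_widths) != 3:
            raise ValueError("depths/heads/stripe_widths must each have 3 encoder-stage entries")
        if len(self.dec_depths) != 2:
            raise ValueError("dec_depths must have 2 decoder-stage entries")

    def block_spec(self) -> BlockSpec:
        return BlockSpec(mlp_ratio=self.mlp_ratio, use_lepe=self.use_lepe)


@dataclass
class PredictionMaps:
    """Network outputs: full-resolution logits (B, N, H, W) and the two
    auxiliary N-channel maps at H/8 and H/4."""

    logits: Tensor
    aux: list = field(default_factory=list)


class CTSNet(Module):
    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        spec = spec or NetworkSpec()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        bs = spec.block_spec()

        self.embed = ConvEmbed(spec.in_channels, c, rng)
        self.enc1 = [CSWinBlock(c, spec.heads[0], spec.stripe_widths[0], rng, bs)
                     for _ in range(spec.depths[0])]
        self.merge1 = PatchMerge(c, rng)
        self.enc2 = [CSWinBlock(2 * c, spec.heads[1], spec.stripe_widths[1], rng, bs)
                     for _ in range(spec.depths[1])]
        self.merge2 = PatchMerge(2 * c, rng)
        self.enc3 = [CSWinBlock(4 * c, spec.heads[2], spec.stripe_widths[2], rng, bs)
                     for _ in range(spec.depths[2])]

        self.expand1 = PatchExpand(4 * c, rng)          # H/16 -> H/8, 4C -> 2C
        self.fuse1 = Linear(4 * c, 2 * c, rng)
        self.dec1 = [CSWinBlock(2 * c, spec.heads[1], spec.stripe_widths[1], rng, bs)
                     for _ in range(spec.dec_depths[0])]
        self.aux_head1 = Linear(2 * c, spec.n_classes, rng)

        self.expand2 = PatchExpand(2 * c, rng)          # H/8 -> H/4, 2C -> C
        self.fuse2 = Linear(2 * c, c, rng)
        self.dec2 = [CSWinBlock(c, spec.heads[0], spec.stripe_widths[0], rng, bs)
                     for _ in range(spec.dec_depths[1])]
        self.aux_head2 = Linear(c, spec.n_classes, rng)

        self.final_expand = FinalPatchExpand(c, rng)    # H/4 -> H, C -> C
        self.head = Linear(c, spec.n_classes, rng)

        # zero-init every residual branch's output projection and the
        # class heads: blocks start as identities and the initial class
        # distribution is uniform, which substantially speeds and
        # stabilises from-scratch SGD training of this transformer
        for blk in (self.enc1 + self.enc2 + self.enc3 + self.dec1 + self.dec2):
            blk.attn.proj.weight.data[:] = 0.0
            blk.mlp.fc2.weight.data[:] = 0.0
        for head in (self.head, self.aux_head1, self.aux_head2):
            head.weight.data[:] = 0.0

    def forward(self, images: np.ndarray | Tensor) -> PredictionMaps:
        """Segment a batch of square grayscale tiles.

        ``images``: (B, H, W) or (B, H, W, C_in), with H and W divisible
        by 16.  Returns logits (B, N, H, W) plus the H/8 and H/4
        auxiliary maps, each (B, N, h, w).
        """
        if not isinstance(images, Tensor):
            images = np.asarray(images, dtype=float)
            if images.ndim == 3:
                images = images[..., None]
            images = Tensor(images)
        b, h, w = images.shape[:3]
        if h % 16 or w % 16:
            raise ValueError(
                f"input sides must be divisible by 16 (stride-4 embedding plus two "
                f"2x mergings); got {h}x{w}"
            )

        x = self.embed(images)                 # (B, H/4, W/4, C)
        for blk in self.enc1:
            x = blk(x)
        skip1 = x
        x = self.merge1(x)                     # (B, H/8, W/8, 2C)
        for blk in self.enc2:
            x = blk(x)
        skip2 = x
        x = self.merge2(x)                     # (B, H/16, W/16, 4C)
        for blk in self.enc3:
            x = blk(x)

        x = self.expand1(x)                    # (B, H/8, W/8, 2C)
        x = self.fuse1(concatenate([x, skip2], axis=-1))
        for blk in self.dec1:
            x = blk(x)
        aux1 = self.aux_head1(x).transpose(0, 3, 1, 2)

        x = self.expand2(x)                    # (B, H/4, W/4, C)
        x = self.fuse2(concatenate([x, skip1], axis=-1))
        for blk in self.dec2:
            x = blk(x)
        aux2 = self.aux_head2(x).transpose(0, 3, 1, 2)

        x = self.final_expand(x)               # (B, H, W, C)
        logits = self.head(x).transpose(0, 3, 1, 2)
        return PredictionMaps(logits=logits, aux=[aux1, aux2])

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        import json

        from dataclasses import asdict

        state = self.state_dict()
        state["__spec__"] = np.frombuffer(
            json.dumps(asdict(self.spec)).encode(), dtype=np.uint8
        ).copy()
        np.savez(path, **state)

    @classmethod
    def load(cls, path, seed: int = 0) -> "CTSNet":
        import json

        with np.load(path) as data:
            spec_json = bytes(data["__spec__"]).decode()
            spec_dict = json.loads(spec_json)
            for key in ("depths", "dec_depths", "heads", "stripe_widths"):
                spec_dict[key] = tuple(spec_dict[key])
            net = cls(NetworkSpec(**spec_dict), seed=seed)
            net.load_state_dict({k: v for k, v in data.items() if k != "__spec__"})
        return net


def predict_mask(maps: PredictionMaps | Tensor | np.ndarray) -> np.ndarray:
    """Per-pixel argmax class map; ties break toward the lower class index.

    Accepts a :class:`PredictionMaps` or a raw (B, N, H, W) / (N, H, W)
    logit array; returns int masks of shape (B, H, W) / (H, W).
    """
    logits = maps.logits if isinstance(maps, PredictionMaps) else maps
    if isinstance(logits, Tensor):
        logits = logits.data
    logits = np.asarray(logits)
    axis = 0 if logits.ndim == 3 else 1
    if not np.isfinite(logits).all():
        raise ValueError("logits contain non-finite values")
    return np.argmax(logits, axis=axis).astype(np.int64)
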