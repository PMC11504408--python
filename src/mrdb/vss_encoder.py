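"""State-space encoder branch: patch-embed stem plus four VSS-block stages.

The pyramid is shape-congruent with the residual branch: for input side S
the stage outputs have sides (S/4, S/8, S/16, S/32) and channel counts
(w, 2w, 4w, 8w).  A 4×4 stride-4 patch embedding reaches S/4; stride-2
patch merging halves the side and doubles the width between stages.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .autograd.nn import Conv2d, LayerNorm2d, Module
from .resnet_encoder import EncoderPyramid
from .ssm2d import VSSBlock

__all__ = ["VSSEncoder", "vss_encode"]


class _PatchMerge(Module):
    """Stride-2 2×2 convolution doubling the channel count, plus layer norm."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(channels, 2 * channels, 2, stride=2, rng=rng)
        self.norm = LayerNorm2d(2 * channels)

    def forward(self, x) -> Tensor:
        return self.norm(self.conv(x))


class VSSEncoder(Module):
    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 blocks_per_stage: int = 2, state_dim: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = base_channels
        self.base_channels = w
        self.patch_embed = Conv2d(in_channels, w, 4, stride=4, rng=rng)
        self.embed_norm = LayerNorm2d(w)
        self._stages: list[list[VSSBlock]] = []
        self._merges: list[_PatchMerge | None] = []
        width = w
        for si in range(4):
            blocks = [VSSBlock(width, state_dim=state_dim, rng=rng)
                      for _ in range(blocks_per_stage)]
            for bi, blk in enumerate(blocks):
                setattr(self, f"stage{si + 1}_{bi}", blk)
            self._stages.append(blocks)
            if si < 3:
                merge = _PatchMerge(width, rng=rng)
                setattr(self, f"merge{si + 1}", merge)
                self._merges.append(merge)
                width *= 2
            else:
                self._merges.append(None)

    def forward(self, image) -> EncoderPyramid:
        image = as_tensor(image)
        side = image.shape[-1]
        if image.shape[-2] != side or side % 32 != 0:
            raise ValueError(f"input side must be square and divisible by 32, got {image.shape}")
        x = self.embed_norm(self.patch_embed(image))
        outs = []
        for blocks, merge in zip(self._stages, self._merges):
            for blk in blocks:
                x = blk(x)
            outs.append(x)
            if merge is not None:
                x = merge(x)
        return EncoderPyramid(stages=outs, branch_tag="VSSB")


def vss_encode(image, encoder: VSSEncoder) -> EncoderPyramid:
    """Functional form of :meth:`VSSEncoder.forward`."""
    return encoder(image)
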