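"""Asymmetric decoder stages.

Both stage types double the spatial side and halve the channel count, but
differ in operation order:

* left  — transpose-conv, 3×3 conv, 3×3 conv (upsample first, then refine)
* right — 3×3 conv, transpose-conv, 3×3 conv (refine first, then upsample)

An optional ``fuse`` callable is applied right after upsampling, which is
where skip features enter at the matching resolution.  ``DecoderHead``
recovers the remaining ×2 of resolution and maps to 1-channel logits.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .autograd import Tensor, as_tensor
from .autograd.nn import BatchNorm2d, Conv2d, ConvTranspose2d, Module, Sequential, ReLU

__all__ = ["LeftDecoderStage", "RightDecoderStage", "DecoderHead",
           "left_decoder_stage", "right_decoder_stage"]


def _conv_bn_relu(cin: int, cout: int, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, padding=1, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class LeftDecoderStage(Module):
    """Upsample–convolve–convolve stage (rapid resolution recovery)."""

    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        out = in_channels // 2
        self.up = ConvTranspose2d(in_channels, out, 2, stride=2, rng=rng)
        self.conv_a = _conv_bn_relu(out, out, rng)
        self.conv_b = _conv_bn_relu(out, out, rng)
        self.in_channels, self.out_channels = in_channels, out

    def forward(self, x, fuse: Callable[[Tensor], Tensor] | None = None) -> Tensor:
        x = self.up(as_tensor(x))
        if fuse is not None:
            x = fuse(x)
        return self.conv_b(self.conv_a(x))


class RightDecoderStage(Module):
    """Convolve–upsample–convolve stage (gradual feature refinement)."""

    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        out = in_channels // 2
        self.conv_a = _conv_bn_relu(in_channels, in_channels, rng)
        self.up = ConvTranspose2d(in_channels, out, 2, stride=2, rng=rng)
        self.conv_b = _conv_bn_relu(out, out, rng)
        self.in_channels, self.out_channels = in_channels, out

    def forward(self, x, fuse: Callable[[Tensor], Tensor] | None = None) -> Tensor:
        x = self.up(self.conv_a(as_tensor(x)))
        if fuse is not None:
            x = fuse(x)
        return self.conv_b(x)


class DecoderHead(Module):
    """Final ×2 transpose-conv plus 1×1 conv to single-channel logits."""

    def __init__(self, in_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        mid = max(in_channels // 2, 8)
        self.up = ConvTranspose2d(in_channels, mid, 2, stride=2, rng=rng)
        self.bn = BatchNorm2d(mid)
        self.out = Conv2d(mid, 1, 1, rng=rng)

    def forward(self, x) -> Tensor:
        return self.out(self.bn(self.up(as_tensor(x))).relu())


def left_decoder_stage(x, stage: LeftDecoderStage) -> Tensor:
    """Functional form of :meth:`LeftDecoderStage.forward` (no skip)."""
    return stage(x)


def right_decoder_stage(x, stage: RightDecoderStage) -> Tensor:
    """Functional form of :meth:`RightDecoderStage.forward` (no skip)."""
    return stage(x)
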