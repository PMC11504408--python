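"""ResNet-34 encoder branch (classification head removed).

Layout: 7×7 stride-2 stem convolution, 3×3 stride-2 max pool, then four
stages of basic residual blocks with block counts 3/4/6/3.  For an input
of side S the stage outputs have sides (S/4, S/8, S/16, S/32) and channel
counts (w, 2w, 4w, 8w) for stem width w (64 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .autograd.nn import BatchNorm2d, Conv2d, MaxPool2d, Module

__all__ = ["BasicBlock", "ResNetEncoder", "EncoderPyramid", "resnet34_encode",
           "BLOCK_COUNTS"]

#: Basic-block counts of the four stages (the 34-layer configuration).
BLOCK_COUNTS = (3, 4, 6, 3)


@dataclass
class EncoderPyramid:
    """Ordered multi-resolution encoder outputs, shallow to deep."""

    stages: list[Tensor]
    branch_tag: str

    def shapes(self) -> list[tuple[int, ...]]:
        return [s.shape for s in self.stages]


class BasicBlock(Module):
    """Two 3×3 convolutions with a residual shortcut: ``y = ReLU(F(x) + x)``.

    ``F(x) = W2 · ReLU(W1 · x)`` (with a batch norm after each conv); a
    stride-2 projection shortcut is used when the block downsamples or
    changes width.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, stride=1, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.down_conv = Conv2d(in_channels, out_channels, 1, stride=stride,
                                    bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_channels)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        f = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        if f.shape != shortcut.shape:
            raise ValueError(f"residual shapes differ: {f.shape} vs {shortcut.shape}")
        return (f + shortcut).relu()


def basic_block_forward(x, block: BasicBlock) -> Tensor:
    """Functional form of :meth:`BasicBlock.forward`."""
    return block(x)


class ResNetEncoder(Module):
    """Headless ResNet-34 trunk producing a four-stage feature pyramid."""

    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = base_channels
        self.base_channels = w
        self.conv1 = Conv2d(in_channels, w, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(w)
        self.maxpool = MaxPool2d(3, stride=2, padding=1)
        widths = (w, 2 * w, 4 * w, 8 * w)
        stages = []
        in_w = w
        for si, (width, count) in enumerate(zip(widths, BLOCK_COUNTS)):
            blocks = []
            for bi in range(count):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(BasicBlock(in_w, width, stride=stride, rng=rng))
                in_w = width
            stages.append(blocks)
        for si, blocks in enumerate(stages):
            for bi, blk in enumerate(blocks):
                setattr(self, f"layer{si + 1}_{bi}", blk)
        self._stage_blocks = stages

    def stem(self, image) -> Tensor:
        """Stem convolution output (before pooling); side S/2 for input side S."""
        return self.bn1(self.conv1(as_tensor(image))).relu()

    def forward(self, image) -> EncoderPyramid:
        image = as_tensor(image)
        side = image.shape[-1]
        if image.shape[-2] != side or side % 32 != 0:
            raise ValueError(f"input side must be square and divisible by 32, got {image.shape}")
        x = self.maxpool(self.stem(image))
        outs = []
        for blocks in self._stage_blocks:
            for blk in blocks:
                x = blk(x)
            outs.append(x)
        return EncoderPyramid(stages=outs, branch_tag="ResNet")


def resnet34_encode(image, encoder: ResNetEncoder) -> EncoderPyramid:
    """Functional form of :meth:`ResNetEncoder.forward`."""
    return encoder(image)
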