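"""Dual-branch segmentation network assembly.

The full model couples a state-space encoder (global context) and a
ResNet-34 encoder (local detail) through a shared bottleneck, decodes with
two asymmetric decoder branches, and routes skip features crosswise:
state-space encoder stages are *added* into the right decoder, residual
encoder stages are *concatenated* (then channel-reduced) into the left
decoder.  The two full-resolution logit maps are fused by a 1×1
convolution and a sigmoid.

Every architectural ingredient is an independent switch on
:class:`MRDBConfig`, so the six ablation configurations (plain UNet →
dual UNet → +cross skips → +ResNet-34 → +right decoder → +VSSB) are all
instances of the same class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat
from .autograd.nn import (
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Module,
    PointwiseLinear,
    ReLU,
    Sequential,
)
from .decoders import DecoderHead, LeftDecoderStage, RightDecoderStage
from .resnet_encoder import EncoderPyramid, ResNetEncoder
from .vss_encoder import VSSEncoder

__all__ = [
    "MRDBConfig",
    "CrossSkipRule",
    "CrossSkipFuse",
    "FuseOutputs",
    "ConvEncoder",
    "DecoderBranch",
    "MRDB",
    "cross_skip_fuse",
    "fuse_outputs",
    "mrdb_forward",
]


@dataclass
class MRDBConfig:
    """Architecture and ablation switches.

    With every ``*_enabled`` flag off the model collapses to a single
    plain convolutional UNet; enabling them in order reproduces the
    ablation ladder up to the full dual-branch model.
    """

    input_side: int = 256
    in_channels: int = 1
    base_channels: int = 64
    dual_unet_enabled: bool = True
    csc_enabled: bool = True
    resnet_enabled: bool = True
    r_decoder_enabled: bool = True
    vssb_enabled: bool = True
    state_dim: int = 16
    blocks_per_vss_stage: int = 2
    pretrained: bool = False
    fusion: str = "conv"  # or "average"
    seed: int = 0

    def __post_init__(self):
        if self.input_side % 32 != 0:
            raise ValueError(f"input_side must be divisible by 32, got {self.input_side}")
        if self.pretrained:
            raise NotImplementedError("pretrained initialisation is not bundled")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MRDBConfig":
        return cls(**d)


@dataclass
class CrossSkipRule:
    """How one encoder stage feeds a decoder stage."""

    source_branch: str  # "VSSB" | "ResNet"
    depth_index: int
    mode: str = ""  # "add" | "concat"; derived from source_branch if empty

    def __post_init__(self):
        if not self.mode:
            self.mode = "add" if self.source_branch == "VSSB" else "concat"


class CrossSkipFuse(Module):
    """Skip-fusion operator: element-wise addition, or concatenation
    followed by a 3×3 convolution reducing back to the decoder width."""

    def __init__(self, mode: str, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if mode not in ("add", "concat"):
            raise ValueError(f"unknown fuse mode {mode!r}")
        self.mode, self.channels = mode, channels
        if mode == "concat":
            self.reduce = Conv2d(2 * channels, channels, 3, padding=1, rng=rng)
            self.bn = BatchNorm2d(channels)
        else:
            self.reduce = None

    def forward(self, enc_feat, dec_feat) -> Tensor:
        enc_feat, dec_feat = as_tensor(enc_feat), as_tensor(dec_feat)
        if enc_feat.shape[-2:] != dec_feat.shape[-2:]:
            raise ValueError(f"spatial mismatch: {enc_feat.shape} vs {dec_feat.shape}")
        if self.mode == "add":
            if enc_feat.shape[1] != dec_feat.shape[1]:
                raise ValueError(
                    f"addition requires equal channel counts: {enc_feat.shape[1]} vs {dec_feat.shape[1]}")
            return enc_feat + dec_feat
        stacked = concat([enc_feat, dec_feat], axis=1)
        return self.bn(self.reduce(stacked)).relu()


def cross_skip_fuse(enc_feat, dec_feat, rule: CrossSkipRule,
                    fuser: CrossSkipFuse | None = None) -> Tensor:
    """Apply a cross-skip rule.

    Addition needs no weights; concatenation returns the raw
    channel-stacked map unless a weighted ``fuser`` is supplied to perform
    the channel reduction.
    """
    enc_feat, dec_feat = as_tensor(enc_feat), as_tensor(dec_feat)
    if fuser is not None:
        return fuser(enc_feat, dec_feat)
    if enc_feat.shape[-2:] != dec_feat.shape[-2:]:
        raise ValueError(f"spatial mismatch: {enc_feat.shape} vs {dec_feat.shape}")
    if rule.mode == "add":
        if enc_feat.shape[1] != dec_feat.shape[1]:
            raise ValueError("addition requires equal channel counts")
        return enc_feat + dec_feat
    return concat([enc_feat, dec_feat], axis=1)


class FuseOutputs(Module):
    """Combine two full-resolution logit maps into one probability map."""

    def __init__(self, mode: str = "conv", rng: np.random.Generator | None = None):
        super().__init__()
        self.mode = mode
        if mode == "conv":
            self.mix = Conv2d(2, 1, 1, rng=rng)
            # averaging initialisation: identical inputs pass through unchanged
            self.mix.weight.data[:] = 0.5
            self.mix.bias.data[:] = 0.0
        elif mode != "average":
            raise ValueError(f"unknown fusion mode {mode!r}")

    def forward(self, left_map, right_map) -> Tensor:
        left_map, right_map = as_tensor(left_map), as_tensor(right_map)
        if left_map.shape != right_map.shape:
            raise ValueError(f"shape mismatch: {left_map.shape} vs {right_map.shape}")
        if self.mode == "conv":
            return self.mix(concat([left_map, right_map], axis=1)).sigmoid()
        return (left_map.sigmoid() + right_map.sigmoid()) * 0.5


def fuse_outputs(left_map, right_map, fuser: FuseOutputs | None = None) -> Tensor:
    if fuser is None:
        fuser = FuseOutputs("conv")
    return fuser(left_map, right_map)


def _conv_bn_relu(cin: int, cout: int, stride: int, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class ConvEncoder(Module):
    """Plain convolutional encoder with the same pyramid contract as the
    specialised branches (sides S/4..S/32, widths w..8w)."""

    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = base_channels
        self.stem = Sequential(
            _conv_bn_relu(in_channels, w, 2, rng),
            _conv_bn_relu(w, w, 2, rng),
            _conv_bn_relu(w, w, 1, rng),
        )
        self.pool = MaxPool2d(2, stride=2)
        self._stage_mods = []
        for si in range(3):
            cin = w * 2 ** si
            stage = Sequential(_conv_bn_relu(cin, 2 * cin, 1, rng),
                               _conv_bn_relu(2 * cin, 2 * cin, 1, rng))
            setattr(self, f"stage{si + 2}", stage)
            self._stage_mods.append(stage)

    def forward(self, image) -> EncoderPyramid:
        x = self.stem(as_tensor(image))
        outs = [x]
        for stage in self._stage_mods:
            x = stage(self.pool(x))
            outs.append(x)
        return EncoderPyramid(stages=outs, branch_tag="Conv")


class DecoderBranch(Module):
    """Four decoder stages plus a resolution-restoring head.

    ``style`` selects the stage type; ``skip_modes`` gives the fusion mode
    for the three skip-carrying stages (deep to shallow), with ``None``
    meaning no skip.
    """

    def __init__(self, base_channels: int, style: str,
                 skip_modes: tuple[str | None, str | None, str | None],
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = base_channels
        cls = {"left": LeftDecoderStage, "right": RightDecoderStage}[style]
        self.style = style
        ins = [8 * w, 4 * w, 2 * w, w]
        self._stages = []
        self._fusers: list[CrossSkipFuse | None] = []
        for i, cin in enumerate(ins):
            stage = cls(cin, rng=rng)
            setattr(self, f"stage{i}", stage)
            self._stages.append(stage)
            mode = skip_modes[i] if i < 3 else None
            if mode is not None:
                fuser = CrossSkipFuse(mode, cin // 2, rng=rng)
                setattr(self, f"fuse{i}", fuser)
                self._fusers.append(fuser)
            else:
                self._fusers.append(None)
        self.head = DecoderHead(w // 2, rng=rng)

    def forward(self, bottleneck, skips: list[Tensor] | None) -> Tensor:
        """``skips`` lists encoder stages shallow→deep (or ``None``)."""
        x = bottleneck
        for i, (stage, fuser) in enumerate(zip(self._stages, self._fusers)):
            fuse = None
            if fuser is not None and skips is not None:
                enc_feat = skips[2 - i]
                fuse = lambda dec, e=enc_feat, f=fuser: f(e, dec)
            x = stage(x, fuse=fuse)
        return self.head(x)


class MRDB(Module):
    """The assembled segmentation network (all ablation variants)."""

    def __init__(self, cfg: MRDBConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_channels
        ci = cfg.in_channels

        def make_left_encoder():
            if cfg.vssb_enabled:
                return VSSEncoder(ci, w, blocks_per_stage=cfg.blocks_per_vss_stage,
                                  state_dim=cfg.state_dim, rng=rng)
            return ConvEncoder(ci, w, rng=rng)

        def make_right_encoder():
            if cfg.resnet_enabled:
                return ResNetEncoder(ci, w, rng=rng)
            return ConvEncoder(ci, w, rng=rng)

        if not cfg.dual_unet_enabled:
            # single plain UNet: one conv encoder, one upsample-first decoder
            self.encoder = ConvEncoder(ci, w, rng=rng)
            self.decoder = DecoderBranch(w, "left", ("concat",) * 3, rng=rng)
            return

        self.left_encoder = make_left_encoder()
        self.right_encoder = make_right_encoder()
        self.bottleneck = PointwiseLinear(16 * w, 8 * w, rng=rng)
        self.bottleneck_bn = BatchNorm2d(8 * w)
        if cfg.csc_enabled:
            left_modes = ("concat",) * 3   # fed by the residual branch
            right_modes = ("add",) * 3     # fed by the state-space branch
        else:
            left_modes = ("concat",) * 3   # own-side plain skips
            right_modes = ("concat",) * 3
        right_style = "right" if cfg.r_decoder_enabled else "left"
        self.left_decoder = DecoderBranch(w, "left", left_modes, rng=rng)
        self.right_decoder = DecoderBranch(w, right_style, right_modes, rng=rng)
        self.fuse = FuseOutputs(cfg.fusion, rng=rng)

    # ------------------------------------------------------------------ fwd
    def forward(self, image) -> Tensor:
        image = as_tensor(image)
        cfg = self.cfg
        if image.ndim != 4 or image.shape[1] != cfg.in_channels:
            raise ValueError(f"expected (B, {cfg.in_channels}, S, S) input, got {image.shape}")
        if image.shape[-1] != cfg.input_side or image.shape[-2] != cfg.input_side:
            raise ValueError(
                f"expected side {cfg.input_side}, got {image.shape[-2]}x{image.shape[-1]}")

        if not cfg.dual_unet_enabled:
            pyr = self.encoder(image)
            logits = self.decoder(pyr.stages[-1], pyr.stages)
            return logits.sigmoid()

        left_pyr = self.left_encoder(image)
        right_pyr = self.right_encoder(image)
        deep = concat([left_pyr.stages[-1], right_pyr.stages[-1]], axis=1)
        bottleneck = self.bottleneck_bn(self.bottleneck(deep)).relu()
        if cfg.csc_enabled:
            left_skips = right_pyr.stages   # residual features -> left decoder
            right_skips = left_pyr.stages   # state-space features -> right decoder
        else:
            left_skips = left_pyr.stages
            right_skips = right_pyr.stages
        left_logits = self.left_decoder(bottleneck, left_skips)
        right_logits = self.right_decoder(bottleneck, right_skips)
        return self.fuse(left_logits, right_logits)


def mrdb_forward(image, model: MRDB) -> Tensor:
    """Functional form of :meth:`MRDB.forward`."""
    return model(image)
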