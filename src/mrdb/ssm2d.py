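"""2D selective scan (SS2D) and the visual state-space block (VSSB).

The SS2D pipeline unfolds a feature map into four directional 1D sequences
(row-major, column-major and their reversals), runs each through an
input-dependent linear state-space recurrence (the S6 block), folds every
sequence back to its 2D layout and sums the four results.

The recurrence uses zero-order-hold discretization::

    Abar_t = exp(dt_t * A)        A < 0, dt_t = softplus(proj(x_t)) >= 0
    h_t    = Abar_t * h_{t-1} + dt_t * B_t * x_t
    y_t    = C_t . h_t + D * x_t

so discretized transition magnitudes never exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concat, einsum2, linear_scan
from .autograd.nn import (
    DepthwiseConv2d,
    LayerNorm2d,
    Module,
    Parameter,
    PointwiseLinear,
)

__all__ = [
    "PATH_IDS",
    "DirectionalSequences",
    "SSMParams",
    "VSSBlock",
    "scan_expand",
    "scan_merge",
    "selective_scan_s6",
    "ssm_recurrence",
    "ss2d",
    "vssb_forward",
]

#: Traversal order of the four scan paths.
PATH_IDS = ("row", "col", "row_rev", "col_rev")


@dataclass
class DirectionalSequences:
    """Four directional unfoldings of a (B, C, H, W) feature map."""

    sequences: list[Tensor]
    path_ids: tuple[str, ...] = field(default=PATH_IDS)
    height: int = 0
    width: int = 0


def scan_expand(x) -> DirectionalSequences:
    """Unfold a feature map into four directional (B, C, H·W) sequences.

    Paths: row-major, column-major, reversed row-major, reversed
    column-major.  Each sequence is a permutation of the flattened input.
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected a (B, C, H, W) map, got shape {x.shape}")
    b, c, h, w = x.shape
    if h < 1 or w < 1 or c < 1:
        raise ValueError(f"empty spatial or channel dimension in shape {x.shape}")
    row = x.reshape(b, c, h * w)
    col = x.transpose(0, 1, 3, 2).reshape(b, c, h * w)
    return DirectionalSequences(
        sequences=[row, col, row.flip(2), col.flip(2)],
        height=h,
        width=w,
    )


def scan_merge(seqs: DirectionalSequences, height: int, width: int) -> Tensor:
    """Inverse-permute each directional sequence to 2D and sum the four maps."""
    hw = height * width
    maps = []
    for pid, s in zip(seqs.path_ids, seqs.sequences):
        s = as_tensor(s)
        if s.shape[-1] != hw:
            raise ValueError(f"sequence length {s.shape[-1]} != {height}x{width}")
        b, c = s.shape[0], s.shape[1]
        if pid.endswith("_rev"):
            s = s.flip(2)
        if pid.startswith("col"):
            m = s.reshape(b, c, width, height).transpose(0, 1, 3, 2)
        else:
            m = s.reshape(b, c, height, width)
        maps.append(m)
    out = maps[0]
    for m in maps[1:]:
        out = out + m
    return out


class SSMParams(Module):
    """Parameters of one selective state-space (S6) recurrence.

    Holds the state-decay matrix ``A = -exp(A_log)``, the input-dependent
    step-size / input / output projections and the direct feedthrough ``D``.
    Shared across the four scan directions.
    """

    def __init__(self, channels: int, state_dim: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if state_dim < 1:
            raise ValueError("state_dim must be positive")
        self.channels, self.state_dim = channels, state_dim
        # A initialised to -(1..N) per channel, the usual S4/S6 real init.
        self.A_log = Parameter(np.log(np.tile(np.arange(1, state_dim + 1, dtype=np.float32),
                                              (channels, 1))))
        scale = 1.0 / np.sqrt(channels)
        self.dt_proj = Parameter(rng.normal(0, scale, (channels, channels)))
        # bias chosen so softplus(bias) lands in [1e-3, 1e-1]
        dt_init = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), channels))
        self.dt_bias = Parameter(np.log(np.expm1(dt_init)))
        self.B_proj = Parameter(rng.normal(0, scale, (state_dim, channels)))
        self.C_proj = Parameter(rng.normal(0, scale, (state_dim, channels)))
        self.D = Parameter(np.ones(channels))

    def validate(self) -> None:
        for name, p in self.named_parameters():
            if not np.isfinite(p.data).all():
                raise ValueError(f"non-finite values in SSM parameter {name!r}")


def ssm_recurrence(u, delta, A, Bt, Ct, D) -> Tensor:
    """Evaluate the discretized recurrence for explicit coefficient arrays.

    Shapes: ``u, delta`` (B, C, L); ``A`` (C, N); ``Bt, Ct`` (B, N, L);
    ``D`` (C,).  Returns (B, C, L).
    """
    u, delta, A = as_tensor(u), as_tensor(delta), as_tensor(A)
    Bt, Ct, D = as_tensor(Bt), as_tensor(Ct), as_tensor(D)
    b, c, L = u.shape
    n = A.shape[1]
    abar = einsum2("bcl,cn->bcnl", delta, A).exp()
    bu = einsum2("bcl,bnl->bcnl", delta * u, Bt)
    h = linear_scan(abar.reshape(b * c * n, L), bu.reshape(b * c * n, L))
    h = h.reshape(b, c, n, L)
    y = einsum2("bcnl,bnl->bcl", h, Ct)
    return y + D.reshape(1, c, 1) * u


def selective_scan_s6(seq, params: SSMParams) -> Tensor:
    """Input-dependent selective scan over a (B, C, L) sequence."""
    seq = as_tensor(seq)
    if seq.ndim != 3:
        raise ValueError(f"expected (B, C, L) sequence, got shape {seq.shape}")
    if seq.shape[-1] == 0:
        raise ValueError("sequence length must be >= 1")
    params.validate()
    c = params.channels
    delta = (einsum2("dc,bcl->bdl", params.dt_proj, seq)
             + params.dt_bias.reshape(1, c, 1)).softplus()
    A = -(params.A_log.exp())
    Bt = einsum2("nc,bcl->bnl", params.B_proj, seq)
    Ct = einsum2("nc,bcl->bnl", params.C_proj, seq)
    return ssm_recurrence(seq, delta, A, Bt, Ct, params.D)


def ss2d(x, params: SSMParams) -> Tensor:
    """Full scan-expand → S6 → scan-merge pipeline on a (B, C, H, W) map."""
    x = as_tensor(x)
    b = x.shape[0]
    seqs = scan_expand(x)
    stacked = concat(seqs.sequences, axis=0)  # fold directions into batch
    y = selective_scan_s6(stacked, params)
    outs = [y[i * b:(i + 1) * b] for i in range(4)]
    return scan_merge(DirectionalSequences(outs), seqs.height, seqs.width)


class VSSBlock(Module):
    """Visual state-space block.

    ``norm -> {branch A: linear, depth-wise conv, SiLU, SS2D, norm;
    branch B: linear, SiLU} -> product -> output linear -> + input``.
    Input and output channel counts are equal so the residual addition is
    always shape-valid.
    """

    def __init__(self, channels: int, state_dim: int = 16, expand: int = 2,
                 dwconv_kernel: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        inner = channels * expand
        self.channels, self.inner = channels, inner
        self.norm1 = LayerNorm2d(channels)
        self.linear_in_a = PointwiseLinear(channels, inner, rng=rng)
        self.dwconv = DepthwiseConv2d(inner, dwconv_kernel, rng=rng)
        self.ssm = SSMParams(inner, state_dim=state_dim, rng=rng)
        self.norm2 = LayerNorm2d(inner)
        self.linear_in_b = PointwiseLinear(channels, inner, rng=rng)
        self.linear_out = PointwiseLinear(inner, channels, rng=rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        z = self.norm1(x)
        a = self.linear_in_a(z)
        a = self.dwconv(a).silu()
        a = self.norm2(ss2d(a, self.ssm))
        g = self.linear_in_b(z).silu()
        return self.linear_out(a * g) + x


def vssb_forward(x, block: VSSBlock) -> Tensor:
    """Functional form of :meth:`VSSBlock.forward`."""
    return block(x)
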