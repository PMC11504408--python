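"""Minimal neural-network layer library over the autograd engine.

Layers follow the familiar Module pattern: parameters are registered
automatically when assigned as attributes, ``state_dict`` /
``load_state_dict`` give flat name → array views for checkpointing, and
``train()`` / ``eval()`` toggle batch-norm behaviour.

Convolutions are im2col + matmul; transpose convolutions are the exact
adjoint (col2im).  All parameters are float32.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, as_tensor, einsum2

__all__ = [
    "Module",
    "Sequential",
    "Parameter",
    "Conv2d",
    "ConvTranspose2d",
    "DepthwiseConv2d",
    "PointwiseLinear",
    "BatchNorm2d",
    "LayerNorm2d",
    "MaxPool2d",
    "ReLU",
    "SiLU",
    "Sigmoid",
    "Identity",
]


class Parameter(Tensor):
    """A tensor that is registered as trainable."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # ------------------------------------------------------------- traversal
    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # ----------------------------------------------------------- state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for name, _ in list(self.named_buffers()):
            arr = np.asarray(state["buffer:" + name], dtype=np.float32)
            self._assign_buffer(name, arr)

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        mod: Module = self
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod._set_buffer(parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


# ----------------------------------------------------------------- im2col
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, oh, ow): cols has shape (B, C*kh*kw, oh*ow)."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (B, C, oh, ow, kh, kw)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, xshape: tuple[int, int, int, int], kh: int, kw: int,
            stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back into an image)."""
    b, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    img = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            img[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols6[:, :, i, j]
    if pad:
        img = img[:, :, pad:hp - pad, pad:wp - pad]
    return img


class Conv2d(Module):
    """2D convolution (square kernel) with optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.kernel_size = stride, padding, k
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        cols, oh, ow = _im2col(x.data, k, k, s, p)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out_d = np.matmul(wmat, cols).reshape(b, self.out_channels, oh, ow)
        if self.bias is not None:
            out_d += self.bias.data[None, :, None, None]
        prev = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = Tensor(out_d, _prev=prev)
        weight, bias = self.weight, self.bias

        def _bw(g):
            gmat = g.reshape(b, self.out_channels, oh * ow)
            if weight._needs:
                gw = np.einsum("boL,bcL->oc", gmat, cols, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if bias is not None and bias._needs:
                bias._accum(gmat.sum(axis=(0, 2)))
            if x._needs:
                gcols = np.matmul(wmat.T, gmat)
                x._accum(_col2im(gcols, (b, c, h, w), k, k, s, p, oh, ow))

        out._backward = _bw
        return out


class ConvTranspose2d(Module):
    """Transpose convolution; with ``kernel_size=2, stride=2`` it exactly
    doubles the spatial side."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels, k, k), in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.kernel_size = stride, k
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s = self.kernel_size, self.stride
        oh, ow = (h - 1) * s + k, (w - 1) * s + k
        if k == s:  # exact integer upsampling, no overlap trim needed
            oh, ow = h * s, w * s
        wmat = self.weight.data.reshape(self.in_channels, -1)  # (IC, OC*k*k)
        xflat = x.data.reshape(b, c, h * w)
        cols = np.matmul(wmat.T[None], xflat)  # (B, OC*k*k, h*w)
        out_d = _col2im(cols, (b, self.out_channels, oh, ow), k, k, s, 0, h, w)
        if self.bias is not None:
            out_d += self.bias.data[None, :, None, None]
        prev = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        out = Tensor(out_d, _prev=prev)
        weight, bias = self.weight, self.bias

        def _bw(g):
            gcols, goh, gow = _im2col(g, k, k, s, 0)
            if weight._needs:
                gw = np.einsum("bKL,bcL->cK", gcols, xflat, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if bias is not None and bias._needs:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x._needs:
                gx = np.matmul(wmat[None], gcols)
                x._accum(gx.reshape(b, c, h, w))

        out._backward = _bw
        return out


class DepthwiseConv2d(Module):
    """Per-channel ('depth-wise') convolution with 'same' padding."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.weight = Parameter(_kaiming(rng, (channels, k, k), k * k))
        self.bias = Parameter(np.zeros(channels))
        self.kernel_size = k
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        out_d = np.einsum("bchwij,cij->bchw", view, self.weight.data, optimize=True)
        out_d += self.bias.data[None, :, None, None]
        out = Tensor(out_d, _prev=(x, self.weight, self.bias))
        weight, bias = self.weight, self.bias

        def _bw(g):
            if weight._needs:
                weight._accum(np.einsum("bchwij,bchw->cij", view, g, optimize=True))
            if bias._needs:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x._needs:
                gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
                gview = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
                wf = self.weight.data[:, ::-1, ::-1]
                x._accum(np.einsum("bchwij,cij->bchw", gview, wf, optimize=True))

        out._backward = _bw
        return out


class PointwiseLinear(Module):
    """Linear map over the channel axis of a (B, C, H, W) map (a 1×1 conv)."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels), in_channels))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        out = einsum2("oc,bchw->bohw", self.weight, x)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_channels, 1, 1)
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.eps, self.momentum, self.channels = eps, momentum, channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self._set_buffer("running_mean",
                             (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(c))
            self._set_buffer("running_var",
                             (1 - self.momentum) * self.running_var + self.momentum * unbiased)
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - mu) * inv[None, :, None, None]
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm2d(Module):
    """Layer normalization over the channel axis of a (B, C, H, W) map."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps, self.channels = eps, channels

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        c = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        xhat = centered * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b_, c_, oh, ow = view.shape[:4]
        flat = view.reshape(b, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out_d = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        out = Tensor(np.ascontiguousarray(out_d), _prev=(x,))

        def _bw(g):
            if not x._needs:
                return
            gp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
            ki, kj = np.unravel_index(idx, (k, k))
            oi = np.arange(oh)[None, None, :, None] * s
            oj = np.arange(ow)[None, None, None, :] * s
            bi = np.arange(b)[:, None, None, None]
            ci = np.arange(c)[None, :, None, None]
            np.add.at(gp, (bi, ci, oi + ki, oj + kj), g)
            x._accum(gp[:, :, p:p + h, p:p + w])

        out._backward = _bw
        return out
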