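"""Minimal inference-only convolutional network engine on NumPy.

Implements the handful of layer types the two backbones need — 2-D
convolution (dense, grouped, depthwise), frozen batch normalization, ReLU,
non-overlapping max pooling, and a residual wrapper — each with a forward
pass and a vector-Jacobian product with respect to the *input* (weights are
never trained here; the input gradient is what the effective-receptive-field
probe consumes).

Conventions: activations are ``(batch, channel, row, col)`` float64 arrays;
convolution kernels are ``(out_channels, in_channels // groups, k, k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DTYPE = np.float64


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of a square 2-D convolution."""

    kernel_size: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: int = 0
    groups: int = 1
    has_bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("kernel_size and channel counts must be positive")
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} must divide in_channels={self.in_channels} "
                f"and out_channels={self.out_channels}"
            )

    @property
    def is_depthwise(self) -> bool:
        return self.groups == self.in_channels == self.out_channels

    def weight_shape(self) -> tuple[int, int, int, int]:
        return (
            self.out_channels,
            self.in_channels // self.groups,
            self.kernel_size,
            self.kernel_size,
        )

    def out_size(self, size: int) -> int:
        out = (size + 2 * self.padding - self.kernel_size) // self.stride + 1
        if out < 1:
            raise ValueError(
                f"kernel {self.kernel_size}/stride {self.stride}/padding "
                f"{self.padding} collapses a {size}-pixel input"
            )
        return out


# ---------------------------------------------------------------------------
# windowing helpers


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding ``k x k`` windows of a padded batch -> (B, C, Ho, Wo, k, k)."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def _scatter_windows(
    gwin: np.ndarray, in_shape: tuple[int, ...], k: int, stride: int, padding: int
) -> np.ndarray:
    """Adjoint of `_windows`: accumulate window gradients back onto the input."""
    b, c, h, w = in_shape
    gxp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=gwin.dtype)
    ho, wo = gwin.shape[2], gwin.shape[3]
    for u in range(k):
        for v in range(k):
            gxp[:, :, u : u + ho * stride : stride, v : v + wo * stride : stride] += (
                gwin[:, :, :, :, u, v]
            )
    if padding:
        gxp = gxp[:, :, padding:-padding, padding:-padding]
    return gxp


# ---------------------------------------------------------------------------
# layers


class Layer:
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, object]:
        raise NotImplementedError

    def backward(self, gy: np.ndarray, cache: object) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, spec: ConvSpec, weight: np.ndarray, bias: np.ndarray | None = None):
        weight = np.asarray(weight, dtype=DTYPE)
        if weight.shape != spec.weight_shape():
            raise ValueError(
                f"weight shape {weight.shape} != expected {spec.weight_shape()}"
            )
        if spec.has_bias:
            if bias is None:
                bias = np.zeros(spec.out_channels, dtype=DTYPE)
            bias = np.asarray(bias, dtype=DTYPE)
            if bias.shape != (spec.out_channels,):
                raise ValueError(f"bias shape {bias.shape} != ({spec.out_channels},)")
        else:
            bias = None
        self.spec = spec
        self.weight = weight
        self.bias = bias

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, received {c}"
            )
        return (self.spec.out_channels, self.spec.out_size(h), self.spec.out_size(w))

    def forward(self, x):
        s = self.spec
        if x.shape[1] != s.in_channels:
            raise ValueError(
                f"expected {s.in_channels} input channels, received {x.shape[1]}"
            )
        if s.is_depthwise:
            # shift-and-accumulate: O(output) memory even for very large kernels
            xp = _pad(x, s.padding)
            k, st = s.kernel_size, s.stride
            ho = s.out_size(x.shape[2])
            wo = s.out_size(x.shape[3])
            y = np.zeros((x.shape[0], s.out_channels, ho, wo), dtype=x.dtype)
            w = self.weight[:, 0]
            for u in range(k):
                for v in range(k):
                    y += xp[:, :, u : u + ho * st : st, v : v + wo * st : st] * w[
                        :, u, v
                    ][None, :, None, None]
            if self.bias is not None:
                y += self.bias[None, :, None, None]
            return y, x.shape
        win = _windows(_pad(x, s.padding), s.kernel_size, s.stride)
        if s.groups == 1:
            b_, c, ho, wo, k, _ = win.shape
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b_ * ho * wo, c * k * k)
            wm = self.weight.reshape(s.out_channels, -1)
            y = (cols @ wm.T).reshape(b_, ho, wo, s.out_channels).transpose(0, 3, 1, 2)
        else:
            cg_in = s.in_channels // s.groups
            cg_out = s.out_channels // s.groups
            parts = []
            for g in range(s.groups):
                wg = win[:, g * cg_in : (g + 1) * cg_in]
                b_, c, ho, wo, k, _ = wg.shape
                cols = wg.transpose(0, 2, 3, 1, 4, 5).reshape(b_ * ho * wo, c * k * k)
                wm = self.weight[g * cg_out : (g + 1) * cg_out].reshape(cg_out, -1)
                parts.append(
                    (cols @ wm.T).reshape(b_, ho, wo, cg_out).transpose(0, 3, 1, 2)
                )
            y = np.concatenate(parts, axis=1)
        if self.bias is not None:
            y = y + self.bias[None, :, None, None]
        return np.ascontiguousarray(y), x.shape

    def backward(self, gy, cache):
        in_shape = cache
        s = self.spec
        if s.is_depthwise:
            b_, c, h, w = in_shape
            k, st, p = s.kernel_size, s.stride, s.padding
            ho, wo = gy.shape[2], gy.shape[3]
            gxp = np.zeros((b_, c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
            wk = self.weight[:, 0]
            for u in range(k):
                for v in range(k):
                    gxp[:, :, u : u + ho * st : st, v : v + wo * st : st] += (
                        gy * wk[:, u, v][None, :, None, None]
                    )
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            return gxp
        if s.groups == 1:
            b_, co, ho, wo = gy.shape
            wm = self.weight.reshape(co, -1)
            gcols = gy.transpose(0, 2, 3, 1).reshape(-1, co) @ wm
            k = s.kernel_size
            gwin = gcols.reshape(b_, ho, wo, s.in_channels, k, k).transpose(
                0, 3, 1, 2, 4, 5
            )
        else:
            cg_in = s.in_channels // s.groups
            cg_out = s.out_channels // s.groups
            b_, _, ho, wo = gy.shape
            k = s.kernel_size
            gwin = np.empty((b_, s.in_channels, ho, wo, k, k), dtype=gy.dtype)
            for g in range(s.groups):
                wm = self.weight[g * cg_out : (g + 1) * cg_out].reshape(cg_out, -1)
                gcols = (
                    gy[:, g * cg_out : (g + 1) * cg_out]
                    .transpose(0, 2, 3, 1)
                    .reshape(-1, cg_out)
                    @ wm
                )
                gwin[:, g * cg_in : (g + 1) * cg_in] = gcols.reshape(
                    b_, ho, wo, cg_in, k, k
                ).transpose(0, 3, 1, 2, 4, 5)
        return _scatter_windows(gwin, in_shape, s.kernel_size, s.stride, s.padding)


class BatchNorm2d(Layer):
    """Frozen (inference-mode) per-channel affine normalization."""

    def __init__(self, scale, shift, mean, var, eps: float = 1e-5):
        self.scale = np.asarray(scale, dtype=DTYPE)
        self.shift = np.asarray(shift, dtype=DTYPE)
        self.mean = np.asarray(mean, dtype=DTYPE)
        self.var = np.asarray(var, dtype=DTYPE)
        if np.any(self.var < 0):
            raise ValueError("running variance must be non-negative")
        self.eps = float(eps)

    @property
    def effective_scale(self) -> np.ndarray:
        return self.scale / np.sqrt(self.var + self.eps)

    @property
    def effective_shift(self) -> np.ndarray:
        return self.shift - self.mean * self.effective_scale

    def out_shape(self, shape):
        return shape

    def forward(self, x):
        g = self.effective_scale
        return x * g[None, :, None, None] + self.effective_shift[None, :, None, None], None

    def backward(self, gy, cache):
        return gy * self.effective_scale[None, :, None, None]


class ReLU(Layer):
    def out_shape(self, shape):
        return shape

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, gy, cache):
        return gy * cache


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride), floor semantics."""

    def __init__(self, kernel_size: int = 2):
        if kernel_size < 1:
            raise ValueError("kernel_size must be positive")
        self.k = kernel_size

    def out_shape(self, shape):
        c, h, w = shape
        if h < self.k or w < self.k:
            raise ValueError(f"{self.k}x{self.k} pool collapses a {h}x{w} input")
        return (c, h // self.k, w // self.k)

    def forward(self, x):
        b, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        xt = (
            x[:, :, : ho * k, : wo * k]
            .reshape(b, c, ho, k, wo, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho, wo, k * k)
        )
        idx = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        return y, (x.shape, idx)

    def backward(self, gy, cache):
        (b, c, h, w), idx = cache
        k = self.k
        ho, wo = h // k, w // k
        gt = np.zeros((b, c, ho, wo, k * k), dtype=gy.dtype)
        np.put_along_axis(gt, idx[..., None], gy[..., None], axis=-1)
        gx = np.zeros((b, c, h, w), dtype=gy.dtype)
        gx[:, :, : ho * k, : wo * k] = (
            gt.reshape(b, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho * k, wo * k)
        )
        return gx


class Residual(Layer):
    """y = x + body(x); the body is a sequential list of layers."""

    def __init__(self, body: list[Layer]):
        self.body = body

    def out_shape(self, shape):
        s = shape
        for layer in self.body:
            s = layer.out_shape(s)
        if s != shape:
            raise ValueError("residual body must preserve shape")
        return shape

    def forward(self, x):
        caches = []
        y = x
        for layer in self.body:
            y, c = layer.forward(y)
            caches.append(c)
        return x + y, caches

    def backward(self, gy, cache):
        g = gy
        for layer, c in zip(reversed(self.body), reversed(cache)):
            g = layer.backward(g, c)
        return gy + g


class Sequential(Layer):
    def __init__(self, body: list[Layer]):
        self.body = body

    def out_shape(self, shape):
        for layer in self.body:
            shape = layer.out_shape(shape)
        return shape

    def forward(self, x):
        caches = []
        for layer in self.body:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, gy, cache):
        for layer, c in zip(reversed(self.body), reversed(cache)):
            gy = layer.backward(gy, c)
        return gy


# ---------------------------------------------------------------------------
# initialization


def he_conv(rng: np.random.Generator, spec: ConvSpec) -> np.ndarray:
    """He/fan-in normal initialization, the standard choice for ReLU nets."""
    fan_in = (spec.in_channels // spec.groups) * spec.kernel_size**2
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), spec.weight_shape()).astype(DTYPE)
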