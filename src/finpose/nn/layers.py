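"""Minimal CPU neural-network layers with explicit forward/backward passes.

The pose network needs only a small set of operations -- pointwise and
depthwise convolutions, strided and transposed convolutions, pixel
shuffle/unshuffle, four normalization flavors, hard-swish activations,
squeeze-and-excitation, and spatial dropout -- so they are implemented
directly on numpy arrays with hand-derived gradients.  All layers follow the
same protocol::

    y = layer.forward(x, training=..., rng=...)   # caches what backward needs
    gx = layer.backward(gy)                       # accumulates param.grad

Gradients accumulate across calls until ``zero_grad``; this is what makes
gradient accumulation over micro-batches a first-class citizen.  Every
gradient here is checked against finite differences in the test suite.

Arrays are (batch, channels, height, width), float32 by default (float64 is
supported for gradient checking).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Residual",
    "Conv2d",
    "ConvTranspose2d",
    "Normalization",
    "ReLU",
    "HardSwish",
    "HardSigmoid",
    "SqueezeExcite",
    "SpatialDropout",
    "PixelShuffle",
    "PixelUnshuffle",
    "hard_swish",
    "hard_sigmoid",
]

DEFAULT_DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient buffer."""

    def __init__(self, value: np.ndarray, *, decay: bool = False, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # decoupled weight decay applies (conv weights only)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    """relu6(x + 3) / 6."""
    return np.clip(x + 3.0, 0.0, 6.0) / 6.0


def hard_swish(x: np.ndarray) -> np.ndarray:
    """x * relu6(x + 3) / 6."""
    return x * hard_sigmoid(x)


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def forward(self, x: np.ndarray, *, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Layer):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def layers(self) -> list["Layer"]:
        """All sub-layers, depth first, including self."""
        found: list[Layer] = [self]
        for v in vars(self).values():
            if isinstance(v, Layer):
                found.extend(v.layers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        found.extend(item.layers())
        return found

    # -- symbolic bookkeeping for the memory-footprint accounting ----------
    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        return in_shape

    #: whether this layer's output must be materialized and retained (pure
    #: index rearrangements can be recomputed in place and are excluded).
    materializes = True

    def extra_cache_floats(self, in_shape: tuple[int, int, int]) -> int:
        """Per-sample floats cached for backward beyond the activations."""
        return 0


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.children = list(layers)

    def forward(self, x, *, training=False, rng=None):
        for layer in self.children:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, gy):
        for layer in reversed(self.children):
            gy = layer.backward(gy)
        return gy

    def out_shape(self, in_shape):
        for layer in self.children:
            in_shape = layer.out_shape(in_shape)
        return in_shape


class Residual(Layer):
    """y = x + F(x) with F a Sequential body of equal input/output shape."""

    def __init__(self, body: Layer):
        self.body = body

    def forward(self, x, *, training=False, rng=None):
        return x + self.body.forward(x, training=training, rng=rng)

    def backward(self, gy):
        return gy + self.body.backward(gy)


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


class Conv2d(Layer):
    """2D convolution (cross-correlation), groups of 1 or fully depthwise.

    ``depthwise=True`` requires in_channels == out_channels and applies one
    k x k filter per channel.  ``init_gain``/``init_zero`` annotate how the
    weight-initialization scheme treats this layer; they are consumed by
    ``training.init_weights``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 1,
        stride: int = 1,
        padding: int = 0,
        depthwise: bool = False,
        bias: bool = True,
        init_gain: float = 1.0,
        init_zero: bool = False,
        dtype=DEFAULT_DTYPE,
    ):
        if depthwise and in_channels != out_channels:
            raise ValueError("depthwise conv requires in_channels == out_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.depthwise = depthwise
        self.init_gain = init_gain
        self.init_zero = init_zero
        shape = (out_channels, kernel, kernel) if depthwise else (
            out_channels, in_channels, kernel, kernel
        )
        self.weight = Param(np.zeros(shape, dtype=dtype), decay=True, name="weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), name="bias") if bias else None
        self._xp: np.ndarray | None = None

    @property
    def fan_in(self) -> int:
        c = 1 if self.depthwise else self.in_channels
        return c * self.kernel * self.kernel

    @property
    def fan_out(self) -> int:
        c = 1 if self.depthwise else self.out_channels
        return c * self.kernel * self.kernel

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        return win[:, :, :: self.stride, :: self.stride]

    def forward(self, x, *, training=False, rng=None):
        xp = _pad_hw(x, self.padding)
        self._xp = xp
        win = self._windows(xp)  # (B, C, Ho, Wo, k, k)
        if self.depthwise:
            y = np.einsum("bchwuv,cuv->bchw", win, self.weight.value, optimize=True)
        else:
            y = np.einsum("bchwuv,ocuv->bohw", win, self.weight.value, optimize=True)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, gy):
        xp = self._xp
        win = self._windows(xp)
        if self.depthwise:
            self.weight.grad += np.einsum("bchwuv,bchw->cuv", win, gy, optimize=True)
        else:
            self.weight.grad += np.einsum("bchwuv,bohw->ocuv", win, gy, optimize=True)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        s, ho, wo = self.stride, gy.shape[2], gy.shape[3]
        for u in range(self.kernel):
            for v in range(self.kernel):
                view = gxp[:, :, u : u + s * ho : s, v : v + s * wo : s]
                if self.depthwise:
                    view += gy * self.weight.value[None, :, u, v, None, None]
                else:
                    view += np.einsum(
                        "bohw,oc->bchw", gy, self.weight.value[:, :, u, v], optimize=True
                    )
        p = self.padding
        self._xp = None
        return gxp[:, :, p : gxp.shape[2] - p, p : gxp.shape[3] - p] if p else gxp

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kernel) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel) // self.stride + 1
        return (self.out_channels, ho, wo)


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel == stride (non-overlapping)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 2,
        bias: bool = True,
        init_gain: float = 1.0,
        init_zero: bool = False,
        dtype=DEFAULT_DTYPE,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.init_gain = init_gain
        self.init_zero = init_zero
        self.weight = Param(
            np.zeros((in_channels, out_channels, kernel, kernel), dtype=dtype),
            decay=True,
            name="weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=dtype), name="bias") if bias else None
        self._x: np.ndarray | None = None

    @property
    def fan_in(self) -> int:
        # Each output pixel receives exactly one input pixel per in-channel.
        return self.in_channels

    @property
    def fan_out(self) -> int:
        return self.out_channels

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        b, c, h, w = x.shape
        k = self.kernel
        y6 = np.einsum("bchw,couv->bohuwv", x, self.weight.value, optimize=True)
        y = y6.reshape(b, self.out_channels, h * k, w * k)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, gy):
        x = self._x
        b, c, h, w = x.shape
        k = self.kernel
        gy6 = gy.reshape(b, self.out_channels, h, k, w, k)
        self.weight.grad += np.einsum("bchw,bohuwv->couv", x, gy6, optimize=True)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        self._x = None
        return np.ascontiguousarray(
            np.einsum("bohuwv,couv->bchw", gy6, self.weight.value, optimize=True)
        )

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (self.out_channels, h * self.kernel, w * self.kernel)


class Normalization(Layer):
    """Batch / layer / group / instance normalization with per-channel affine.

    Layer, group, and instance normalization are the batch-size-independent
    family (statistics per sample), implemented as group normalization with 1,
    ``groups``, or C groups.  Batch normalization reduces over (batch, H, W)
    per channel, keeps running statistics with decay ``momentum`` for
    evaluation mode, and is the one flavor whose gradients couple samples.
    Variances are biased (1/N); ``eps`` defaults to 1e-3.
    """

    KINDS = ("batch", "layer", "group", "instance")

    def __init__(
        self,
        num_channels: int,
        kind: str = "instance",
        eps: float = 1e-3,
        momentum: float = 0.9,
        groups: int = 8,
        dtype=DEFAULT_DTYPE,
    ):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if kind == "group" and num_channels % groups:
            raise ValueError("channels must be divisible by the group count")
        self.num_channels = num_channels
        self.kind = kind
        self.eps = eps
        self.momentum = momentum
        self.groups = {"layer": 1, "instance": num_channels, "group": groups}.get(kind, 0)
        self.gamma = Param(np.ones(num_channels, dtype=dtype), name="gamma")
        self.beta = Param(np.zeros(num_channels, dtype=dtype), name="beta")
        if kind == "batch":
            self.running_mean = np.zeros(num_channels, dtype=dtype)
            self.running_var = np.ones(num_channels, dtype=dtype)
        self._cache = None

    def forward(self, x, *, training=False, rng=None):
        b, c, h, w = x.shape
        if self.kind == "batch":
            if training:
                mean = x.mean(axis=(0, 2, 3))
                var = x.var(axis=(0, 2, 3))
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mean.astype(
                    self.running_mean.dtype
                )
                self.running_var = m * self.running_var + (1 - m) * var.astype(
                    self.running_var.dtype
                )
            else:
                mean, var = self.running_mean, self.running_var
            istd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * istd[None, :, None, None]
            self._cache = ("batch", xhat, istd, training)
            return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
                None, :, None, None
            ]
        g = self.groups
        xg = x.reshape(b, g, c // g, h, w)
        mean = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = xg.var(axis=(2, 3, 4), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * istd).reshape(b, c, h, w)
        self._cache = ("group", xhat, istd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, gy):
        b, c, h, w = gy.shape
        kind = self._cache[0]
        if kind == "batch":
            _, xhat, istd, training = self._cache
            self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += gy.sum(axis=(0, 2, 3))
            gxhat = gy * self.gamma.value[None, :, None, None]
            if not training:
                self._cache = None
                return gxhat * istd[None, :, None, None]
            n = b * h * w
            mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            gx = istd[None, :, None, None] * (gxhat - mean_g - xhat * mean_gx)
            self._cache = None
            return gx
        _, xhat, istd = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        g = self.groups
        gxh = gxhat.reshape(b, g, c // g, h, w)
        xh = xhat.reshape(b, g, c // g, h, w)
        mean_g = gxh.mean(axis=(2, 3, 4), keepdims=True)
        mean_gx = (gxh * xh).mean(axis=(2, 3, 4), keepdims=True)
        gx = (istd * (gxh - mean_g - xh * mean_gx)).reshape(b, c, h, w)
        self._cache = None
        return gx

    def extra_cache_floats(self, in_shape):
        c, h, w = in_shape
        return c * h * w  # normalized activations retained for backward


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        gy = gy * self._mask
        self._mask = None
        return gy


class HardSigmoid(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return hard_sigmoid(x)

    def backward(self, gy):
        inside = (self._x > -3.0) & (self._x < 3.0)
        gx = gy * inside / 6.0
        self._x = None
        return gx


class HardSwish(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return hard_swish(x)

    def backward(self, gy):
        x = self._x
        inside = (x > -3.0) & (x < 3.0)
        # d/dx [x * relu6(x+3)/6] = relu6(x+3)/6 + x * 1{-3<x<3}/6
        gx = gy * (hard_sigmoid(x) + x * inside / 6.0)
        self._x = None
        return gx


class SqueezeExcite(Layer):
    """Channel attention: global average pool -> reduce -> expand -> gate.

    MobileNetV3 convention: the pooled vector passes a 4x channel reduction
    with ReLU, then re-expansion with hard sigmoid; the result rescales each
    channel of the input.
    """

    def __init__(self, channels: int, reduction: int = 4, dtype=DEFAULT_DTYPE):
        self.channels = channels
        mid = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, mid, 1, init_gain=np.sqrt(2.0), dtype=dtype)
        self.relu = ReLU()
        self.fc2 = Conv2d(mid, channels, 1, init_gain=np.sqrt(2.0), dtype=dtype)
        self.gate = HardSigmoid()

    def forward(self, x, *, training=False, rng=None):
        b, c, h, w = x.shape
        s = x.mean(axis=(2, 3), keepdims=True)  # (B, C, 1, 1)
        z = self.fc1.forward(s, training=training)
        z = self.relu.forward(z, training=training)
        z = self.fc2.forward(z, training=training)
        g = self.gate.forward(z, training=training)
        self._x, self._g = x, g
        return x * g

    def backward(self, gy):
        x, g = self._x, self._g
        b, c, h, w = x.shape
        gx = gy * g
        gg = (gy * x).sum(axis=(2, 3), keepdims=True)
        gz = self.gate.backward(gg)
        gz = self.fc2.backward(gz)
        gz = self.relu.backward(gz)
        gs = self.fc1.backward(gz)
        gx = gx + gs / (h * w)
        self._x = self._g = None
        return gx

    def extra_cache_floats(self, in_shape):
        # The gating vector and the tiny bottleneck activations; the layer
        # input itself is the previous layer's stored output.
        c, _, _ = in_shape
        return 4 * c


class SpatialDropout(Layer):
    """Channel-wise dropout: zeroes whole feature maps with probability p."""

    def __init__(self, p: float = 0.05):
        if not 0.0 <= p < 1.0:
            raise ValueError("drop probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, *, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("SpatialDropout in training mode needs an rng")
        b, c, _, _ = x.shape
        keep = (rng.random((b, c)) >= self.p).astype(x.dtype) / (1.0 - self.p)
        self._mask = keep[:, :, None, None]
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        gy = gy * self._mask
        self._mask = None
        return gy

    def extra_cache_floats(self, in_shape):
        return in_shape[0]  # one mask entry per channel


class PixelUnshuffle(Layer):
    """Space-to-depth: (C, H, W) -> (C * p^2, H/p, W/p)."""

    materializes = False

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, *, training=False, rng=None):
        b, c, h, w = x.shape
        p = self.factor
        if h % p or w % p:
            raise ValueError(f"spatial dims ({h}, {w}) not divisible by {p}")
        x = x.reshape(b, c, h // p, p, w // p, p)
        return np.ascontiguousarray(x.transpose(0, 1, 3, 5, 2, 4)).reshape(
            b, c * p * p, h // p, w // p
        )

    def backward(self, gy):
        b, cpp, hp, wp = gy.shape
        p = self.factor
        c = cpp // (p * p)
        gy = gy.reshape(b, c, p, p, hp, wp)
        return np.ascontiguousarray(gy.transpose(0, 1, 4, 2, 5, 3)).reshape(
            b, c, hp * p, wp * p
        )

    def out_shape(self, in_shape):
        c, h, w = in_shape
        p = self.factor
        return (c * p * p, h // p, w // p)


class PixelShuffle(Layer):
    """Depth-to-space: (C * p^2, H, W) -> (C, H*p, W*p)."""

    materializes = False

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, *, training=False, rng=None):
        b, cpp, h, w = x.shape
        p = self.factor
        if cpp % (p * p):
            raise ValueError(f"channels ({cpp}) not divisible by {p}^2")
        c = cpp // (p * p)
        x = x.reshape(b, c, p, p, h, w)
        return np.ascontiguousarray(x.transpose(0, 1, 4, 2, 5, 3)).reshape(b, c, h * p, w * p)

    def backward(self, gy):
        b, c, hp, wp = gy.shape
        p = self.factor
        h, w = hp // p, wp // p
        gy = gy.reshape(b, c, h, p, w, p)
        return np.ascontiguousarray(gy.transpose(0, 1, 3, 5, 2, 4)).reshape(
            b, c * p * p, h, w
        )

    def out_shape(self, in_shape):
        c, h, w = in_shape
        p = self.factor
        return (c // (p * p), h * p, w * p)
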