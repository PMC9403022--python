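"""Minimal NumPy layers with explicit forward/backward passes.

Tensors are channels-last: (N, H, W, C), float64.  Convolutions use
'same'-style zero padding so that output spatial dims are ceil(input/stride);
kernels must be odd.  The implementation loops over the k*k kernel taps and
does one strided-slice matmul per tap, which is fast enough for the
desk-scale networks this package trains.
"""

from __future__ import annotations

import numpy as np

from .ops import multichannel_downsample, multichannel_upsample

__all__ = ["Conv2D", "ReLU", "PixelShuffle", "ResUnit", "Sequential"]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        return []


class Conv2D(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        init: str = "he",
        rng: np.random.Generator | None = None,
    ):
        if kernel % 2 == 0:
            raise ValueError("even kernel sizes rejected (centring undefined)")
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.dilation = kernel, stride, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        if init == "he":
            scale = np.sqrt(2.0 / fan_in)
        elif init == "xavier":
            scale = np.sqrt(2.0 / (fan_in + fan_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = rng.normal(0.0, scale, size=(kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def _geometry(self, h: int, w: int):
        eff = self.k + (self.k - 1) * (self.dilation - 1)
        pad = eff // 2
        h_out = (h + 2 * pad - eff) // self.stride + 1
        w_out = (w + 2 * pad - eff) // self.stride + 1
        return eff, pad, h_out, w_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        eff, pad, h_out, w_out = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        y = np.broadcast_to(self.b, (n, h_out, w_out, self.c_out)).copy()
        d, s = self.dilation, self.stride
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i * d : i * d + (h_out - 1) * s + 1 : s, j * d : j * d + (w_out - 1) * s + 1 : s, :]
                y += xs @ self.W[i, j]
        self._cache = (xp, x.shape, (h_out, w_out, pad))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, x_shape, (h_out, w_out, pad) = self._cache
        d, s = self.dilation, self.stride
        dxp = np.zeros_like(xp)
        self.db += grad.sum(axis=(0, 1, 2))
        for i in range(self.k):
            for j in range(self.k):
                sl = (
                    slice(None),
                    slice(i * d, i * d + (h_out - 1) * s + 1, s),
                    slice(j * d, j * d + (w_out - 1) * s + 1, s),
                    slice(None),
                )
                xs = xp[sl]
                self.dW[i, j] += np.einsum("nhwi,nhwo->io", xs, grad)
                dxp[sl] += grad @ self.W[i, j].T
        _, h, w, _ = x_shape
        return dxp[:, pad : pad + h, pad : pad + w, :]


class ReLU(Layer):
    """Leaky rectifier (slope 0.05 on the negative side).  The small leak
    prevents narrow layers from losing the colour channels that separate the
    two tissue classes to dead units, which otherwise traps training in a
    tissue-vs-background plateau."""

    slope = 0.05

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class PixelShuffle(Layer):
    """Sub-pixel upsampling: (N, h, w, r^2 c) -> (N, hr, wr, c); the backward
    pass is the inverse rearrangement."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x):
        return multichannel_upsample(x, self.r)

    def backward(self, grad):
        return multichannel_downsample(grad, self.r)


class ResUnit(Layer):
    """Residual unit: relu(x' + conv2(relu(conv1(x)))) where x' is x or a
    1x1 projection when channel width or stride changes."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        dilation: int = 1,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2D(c_in, c_out, 3, stride=stride, dilation=dilation, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, stride=1, dilation=dilation, rng=rng)
        self.proj = Conv2D(c_in, c_out, 1, stride=stride, rng=rng) if (c_in != c_out or stride != 1) else None
        self.relu_out = ReLU()

    def parameters(self):
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps

    def forward(self, x):
        branch = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(skip + branch)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_skip = self.proj.backward(g) if self.proj is not None else g
        return g_branch + g_skip


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad
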