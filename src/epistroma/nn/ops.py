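"""Reference semantics for the network's building blocks.

`dilated_conv_1d` is the literal sampled-stride convolution
``y[i] = sum_k x[i + r*k] * w[k]`` (valid mode, no padding, 1-indexed taps);
it is kept as the tested reference for the 2-D layers.  `dilated_conv_2d`
is the centred, zero-padded, dimension-preserving 2-D form the layers use.
`multichannel_upsample` is the sub-pixel (pixel-shuffle) rearrangement the
decoder uses to restore full resolution: each low-resolution pixel's
``r*r*c`` channels become an ``r x r`` spatial block with ``c`` channels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "effective_span",
    "dilated_conv_1d",
    "dilated_conv_2d",
    "multichannel_upsample",
    "multichannel_downsample",
]


def effective_span(kernel_len: int, rate: int) -> int:
    """Receptive-field span of a dilated kernel along one axis."""
    return kernel_len + (kernel_len - 1) * (rate - 1)


def dilated_conv_1d(x: np.ndarray, w: np.ndarray, rate: int = 1) -> np.ndarray:
    """Sampled-stride 1-D convolution, valid mode.

    With 1-indexed taps, ``y[i] = sum_{k=1..K} x[i + rate*k] * w[k]`` for all
    i such that every tap lands inside x.
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if x.ndim != 1 or w.ndim != 1:
        raise ValueError("x and w must be 1-D")
    if rate < 1:
        raise ValueError("rate must be >= 1")
    K = len(w)
    n_out = len(x) - rate * K
    if n_out < 1:
        raise ValueError(
            f"input of length {len(x)} too short for kernel span {effective_span(K, rate)} at rate {rate}"
        )
    y = np.zeros(n_out)
    for k in range(1, K + 1):
        y += w[k - 1] * x[rate * k : rate * k + n_out]
    return y


def dilated_conv_2d(image: np.ndarray, kernel: np.ndarray, rate: int = 1) -> np.ndarray:
    """Centred, zero-padded 2-D dilated cross-correlation preserving dims.

    At rate 1 this is ordinary (correlation-oriented) convolution with 'same'
    zero padding.  Even kernel sizes are rejected: centring is undefined.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if image.ndim != 2 or kernel.ndim != 2:
        raise ValueError("image and kernel must be 2-D")
    kh, kw = kernel.shape
    if kh != kw:
        raise ValueError("kernel must be square")
    if kh % 2 == 0:
        raise ValueError("even kernel sizes rejected (centring undefined)")
    if rate < 1:
        raise ValueError("rate must be >= 1")
    pad = rate * (kh - 1) // 2
    padded = np.pad(image, pad, mode="constant")
    h, w = image.shape
    out = np.zeros((h, w))
    for i in range(kh):
        for j in range(kw):
            out += kernel[i, j] * padded[i * rate : i * rate + h, j * rate : j * rate + w]
    return out


def multichannel_upsample(f: np.ndarray, r: int) -> np.ndarray:
    """Rearrange an ``h x w x (r*r*c)`` feature map into ``h*r x w*r x c``.

    Channel block index (p, q) of pixel (i, j) maps to output pixel
    (i*r + p, j*r + q); the map is a bijection of entries (no arithmetic).
    Accepts an optional leading batch axis.
    """
    f = np.asarray(f)
    if r < 1:
        raise ValueError("r must be >= 1")
    batched = f.ndim == 4
    if not batched:
        f = f[None]
    n, h, w, ch = f.shape
    if ch % (r * r) != 0:
        raise ValueError(f"channel count {ch} not divisible by r^2 = {r * r}")
    c = ch // (r * r)
    out = f.reshape(n, h, w, r, r, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h * r, w * r, c)
    return out if batched else out[0]


def multichannel_downsample(f: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of :func:`multichannel_upsample`."""
    f = np.asarray(f)
    if r < 1:
        raise ValueError("r must be >= 1")
    batched = f.ndim == 4
    if not batched:
        f = f[None]
    n, H, W, c = f.shape
    if H % r != 0 or W % r != 0:
        raise ValueError("spatial dims not divisible by r")
    h, w = H // r, W // r
    out = f.reshape(n, h, r, w, r, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, r * r * c)
    return out if batched else out[0]
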