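"""Channel (squeeze-and-excitation) and spatial attention.

Two surfaces are exposed:

* pure functional forms ``se_forward`` / ``spatial_forward`` acting on a single
  C×H×W feature map with explicit parameter structs — handy for unit-level
  reasoning about the gating arithmetic;
* trainable :class:`SEBlock` / :class:`SpatialAttention` modules with full
  backward passes, used inside the classification networks.

SE gating: the feature map is globally average-pooled per channel, squeezed
through a bottleneck ``C -> C/r -> C`` (ReLU between, sigmoid after) and the
resulting per-channel gate in (0, 1) rescales the input channels.

Spatial gating: the channel-wise mean and max maps are concatenated, convolved
with a single 7x7 kernel (padding 3) and passed through a sigmoid, giving one
mask over H×W that rescales every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Module, Parameter
from .layers import Conv2d

__all__ = [
    "SEParams",
    "SpatialParams",
    "se_forward",
    "spatial_forward",
    "SEBlock",
    "SpatialAttention",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SEParams:
    """Bottleneck weights for squeeze-and-excitation gating.

    ``w1`` maps C -> C/r, ``w2`` maps C/r -> C; both carry biases.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    reduction: int

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, np.float32)
        self.w2 = np.asarray(self.w2, np.float32)
        self.b1 = np.asarray(self.b1, np.float32)
        self.b2 = np.asarray(self.b2, np.float32)
        c = self.w1.shape[1]
        if c % self.reduction:
            raise ValueError("reduction must divide the channel count")
        squeeze = c // self.reduction
        if self.w1.shape != (squeeze, c) or self.w2.shape != (c, squeeze):
            raise ValueError("inconsistent SE projection shapes")
        if self.b1.shape != (squeeze,) or self.b2.shape != (c,):
            raise ValueError("inconsistent SE bias shapes")

    @classmethod
    def init(cls, channels: int, reduction: int = 16,
             rng: np.random.Generator | None = None) -> "SEParams":
        rng = rng or np.random.default_rng(0)
        squeeze = channels // reduction
        return cls(
            w1=rng.normal(0, np.sqrt(2.0 / channels), (squeeze, channels)),
            b1=np.zeros(squeeze),
            w2=rng.normal(0, np.sqrt(2.0 / squeeze), (channels, squeeze)),
            b2=np.zeros(channels),
            reduction=reduction,
        )


@dataclass
class SpatialParams:
    """7x7 convolution kernel over [mean; max] channel maps, with bias."""

    kernel: np.ndarray  # (2, 7, 7)
    bias: float

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, np.float32)
        if self.kernel.shape != (2, 7, 7):
            raise ValueError("spatial attention kernel must be 2x7x7")

    @classmethod
    def init(cls, rng: np.random.Generator | None = None) -> "SpatialParams":
        rng = rng or np.random.default_rng(0)
        return cls(kernel=rng.normal(0, np.sqrt(2.0 / 98), (2, 7, 7)), bias=0.0)


def se_forward(feature_map: np.ndarray, params: SEParams) -> np.ndarray:
    """Apply squeeze-and-excitation gating to a C×H×W feature map."""
    f = np.asarray(feature_map, np.float32)
    if f.ndim != 3:
        raise ValueError("feature map must be C×H×W")
    c = f.shape[0]
    if params.w1.shape[1] != c:
        raise ValueError(
            f"SE parameters expect {params.w1.shape[1]} channels, got {c}"
        )
    squeezed = f.mean(axis=(1, 2))
    hidden = np.maximum(params.w1 @ squeezed + params.b1, 0.0)
    gate = _sigmoid(params.w2 @ hidden + params.b2)
    return f * gate[:, None, None]


def spatial_forward(feature_map: np.ndarray, params: SpatialParams) -> np.ndarray:
    """Apply the spatial attention mask to a C×H×W feature map."""
    f = np.asarray(feature_map, np.float32)
    if f.ndim != 3:
        raise ValueError("feature map must be C×H×W")
    mean_map = f.mean(axis=0)
    max_map = f.max(axis=0)
    stacked = np.stack([mean_map, max_map])  # 2×H×W
    padded = np.pad(stacked, ((0, 0), (3, 3), (3, 3)))
    h, w = mean_map.shape
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(padded, (7, 7), axis=(1, 2))  # 2×H×W×7×7
    pre = np.einsum("chwij,cij->hw", windows, params.kernel) + params.bias
    mask = _sigmoid(pre)
    return f * mask[None, :, :]


class SEBlock(Module):
    """Trainable squeeze-and-excitation block (shape-preserving)."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError("reduction must divide the channel count")
        self.channels = channels
        self.reduction = reduction
        rng = rng or np.random.default_rng(0)
        squeeze = channels // reduction
        self.w1 = Parameter(rng.normal(0, np.sqrt(2.0 / channels), (squeeze, channels)))
        self.b1 = Parameter(np.zeros(squeeze, np.float32))
        self.w2 = Parameter(rng.normal(0, np.sqrt(2.0 / squeeze), (channels, squeeze)))
        self.b2 = Parameter(np.zeros(channels, np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        s = x.mean(axis=(2, 3))  # (N, C)
        pre1 = s @ self.w1.data.T + self.b1.data
        h = np.maximum(pre1, 0.0)
        gate = _sigmoid(h @ self.w2.data.T + self.b2.data)
        self._cache = (x, s, pre1, h, gate)
        return x * gate[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, s, pre1, h, gate = self._cache
        n, c, hh, ww = x.shape
        dgate = (grad_out * x).sum(axis=(2, 3))
        dpre2 = dgate * gate * (1.0 - gate)
        self.w2.grad += dpre2.T @ h
        self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.w2.data
        dpre1 = np.where(pre1 > 0, dh, 0.0)
        self.w1.grad += dpre1.T @ s
        self.b1.grad += dpre1.sum(axis=0)
        ds = dpre1 @ self.w1.data
        gx = grad_out * gate[:, :, None, None]
        gx += ds[:, :, None, None] / (hh * ww)
        return gx


class SpatialAttention(Module):
    """Trainable spatial attention mask (single 7x7 conv over [mean; max])."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size != 7:
            raise ValueError("the spatial attention kernel is fixed at 7x7")
        self.conv = Conv2d(2, 1, 7, stride=1, padding=3, bias=True,
                           rng=rng or np.random.default_rng(0))

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean_map = x.mean(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        max_map = np.take_along_axis(x, argmax[:, None], axis=1)
        stacked = np.concatenate([mean_map, max_map], axis=1)
        pre = self.conv(stacked)
        mask = _sigmoid(pre)
        self._cache = (x, argmax, mask)
        return x * mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, argmax, mask = self._cache
        n, c, h, w = x.shape
        dmask = (grad_out * x).sum(axis=1, keepdims=True)
        dpre = dmask * mask * (1.0 - mask)
        dstacked = self.conv.backward(dpre)
        gx = grad_out * mask
        gx += dstacked[:, 0:1] / c  # mean-map path
        gmax = dstacked[:, 1]  # max-map path: route to the argmax channel
        np.put_along_axis(
            gx, argmax[:, None], np.take_along_axis(gx, argmax[:, None], axis=1) + gmax[:, None], axis=1
        )
        return gx
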