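"""Layer primitives: convolution, batch norm, linear, activations, pooling.

Convolution is implemented with :func:`numpy.lib.stride_tricks.sliding_window_view`
plus einsum contractions, with full support for strides, zero padding and
grouped/depthwise kernels.  Backward passes are hand-derived; gradient
correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter

__all__ = [
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "ReLU6",
    "SiLU",
    "Sigmoid",
    "Hardsigmoid",
    "Hardswish",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = int(kernel_size)
        self.stride = int(stride)
        self.padding = int(padding)
        self.groups = int(groups)
        rng = rng or np.random.default_rng(0)
        k = self.kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels // groups, k, k), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None
        self.last_output_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        k, s, p, g = self.kernel_size, self.stride, self.padding, self.groups
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = windows.shape[:4]
        wv = windows.reshape(n, g, c // g, ho, wo, k, k)
        wt = self.weight.data.reshape(g, self.out_channels // g, c // g, k, k)
        out = np.einsum("ngchwij,gkcij->ngkhw", wv, wt, optimize=True)
        out = np.ascontiguousarray(out.reshape(n, self.out_channels, ho, wo))
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (wv, x.shape)
        self.last_output_shape = out.shape
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        wv, padded_shape = self._cache
        n, g = grad_out.shape[0], self.groups
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = grad_out.shape[2:]
        go = grad_out.reshape(n, g, self.out_channels // g, ho, wo)
        dw = np.einsum("ngchwij,ngkhw->gkcij", wv, go, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        wt = self.weight.data.reshape(g, self.out_channels // g, -1, k, k)
        dxp = np.zeros((n, self.in_channels, padded_shape[2], padded_shape[3]), np.float32)
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("ngkhw,gkc->ngchw", go, wt[:, :, :, i, j], optimize=True)
                contrib = contrib.reshape(n, self.in_channels, ho, wo)
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += contrib
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += grad_out.T @ x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            count = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * count / max(count - 1, 1)
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.weight.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.weight.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        g = self.weight.data[None, :, None, None]
        if not self.training:
            return grad_out * g * inv_std[None, :, None, None]
        n = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        gxhat = grad_out * g
        mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv_std[None, :, None, None] * (gxhat - mean_g - xhat * mean_gx)


class ReLU(Module):
    def forward(self, x):
        self._cache = x > 0
        return np.where(self._cache, x, 0.0).astype(np.float32)

    def backward(self, grad_out):
        return np.where(self._cache, grad_out, 0.0)


class ReLU6(Module):
    def forward(self, x):
        self._cache = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0).astype(np.float32)

    def backward(self, grad_out):
        return np.where(self._cache, grad_out, 0.0)


class Sigmoid(Module):
    def forward(self, x):
        out = 1.0 / (1.0 + np.exp(-x))
        self._cache = out
        return out.astype(np.float32)

    def backward(self, grad_out):
        s = self._cache
        return grad_out * s * (1.0 - s)


class SiLU(Module):
    """x * sigmoid(x) (a.k.a. swish)."""

    def forward(self, x):
        s = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, s)
        return (x * s).astype(np.float32)

    def backward(self, grad_out):
        x, s = self._cache
        return grad_out * (s * (1.0 + x * (1.0 - s)))


class Hardsigmoid(Module):
    """clip(x / 6 + 0.5, 0, 1)."""

    def forward(self, x):
        self._cache = (x > -3) & (x < 3)
        return np.clip(x / 6.0 + 0.5, 0.0, 1.0).astype(np.float32)

    def backward(self, grad_out):
        return np.where(self._cache, grad_out / 6.0, 0.0)


class Hardswish(Module):
    """x * hardsigmoid(x)."""

    def forward(self, x):
        self._cache = x
        return (x * np.clip(x / 6.0 + 0.5, 0.0, 1.0)).astype(np.float32)

    def backward(self, grad_out):
        x = self._cache
        d = np.where(x <= -3, 0.0, np.where(x >= 3, 1.0, x / 3.0 + 0.5))
        return grad_out * d


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0,
                 ceil_mode: bool = False):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.ceil_mode = ceil_mode

    def _out_dim(self, d: int) -> int:
        k, s, p = self.kernel_size, self.stride, self.padding
        num = d + 2 * p - k
        out = -(-num // s) + 1 if self.ceil_mode else num // s + 1
        if self.ceil_mode and (out - 1) * s >= d + p:
            out -= 1
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = self._out_dim(h), self._out_dim(w)
        ph = (ho - 1) * s + k - h  # total padding incl. ceil-mode overhang
        pw = (wo - 1) * s + k - w
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (p, max(ph - p, 0)), (p, max(pw - p, 0))),
            constant_values=-np.inf,
        )
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        windows = windows[:, :, :ho, :wo].reshape(n, c, ho, wo, k * k)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape, p)
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, x_shape, xp_shape, p = self._cache
        n, c, ho, wo = grad_out.shape
        k, s = self.kernel_size, self.stride
        dxp = np.zeros(xp_shape, np.float32)
        ii, jj = np.unravel_index(idx, (k, k))
        base_i = np.arange(ho)[None, None, :, None] * s
        base_j = np.arange(wo)[None, None, None, :] * s
        rows = (base_i + ii).ravel()
        cols = (base_j + jj).ravel()
        nn_idx = np.repeat(np.arange(n), c * ho * wo)
        cc_idx = np.tile(np.repeat(np.arange(c), ho * wo), n)
        np.add.at(dxp, (nn_idx, cc_idx, rows, cols), grad_out.ravel())
        return dxp[:, :, p : p + x_shape[2], p : p + x_shape[3]]


class GlobalAvgPool(Module):
    """Spatial mean: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        return np.broadcast_to(
            grad_out[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(np.float32)


class Dropout(Module):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._cache = None
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._cache = mask
        return x * mask

    def backward(self, grad_out):
        if self._cache is None:
            return grad_out
        return grad_out * self._cache


class Flatten(Module):
    def forward(self, x):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._cache)
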