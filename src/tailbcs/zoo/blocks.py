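"""Reusable building blocks shared by the backbone definitions."""

from __future__ import annotations

import numpy as np

from ..nn.core import Module, Parameter, Sequential
from ..nn.layers import (
    BatchNorm2d,
    Conv2d,
    Hardsigmoid,
    Hardswish,
    ReLU,
    ReLU6,
    SiLU,
    Sigmoid,
)

_ACTS = {
    "relu": ReLU,
    "relu6": ReLU6,
    "silu": SiLU,
    "hardswish": Hardswish,
    "sigmoid": Sigmoid,
    "hardsigmoid": Hardsigmoid,
}


def conv_bn_act(
    in_ch: int,
    out_ch: int,
    kernel: int,
    stride: int = 1,
    groups: int = 1,
    act: str | None = "relu",
    rng: np.random.Generator | None = None,
) -> Sequential:
    layers = [
        Conv2d(in_ch, out_ch, kernel, stride=stride, padding=kernel // 2,
               groups=groups, bias=False, rng=rng),
        BatchNorm2d(out_ch),
    ]
    if act is not None:
        layers.append(_ACTS[act]())
    return Sequential(*layers)


class Residual(Module):
    """Identity skip connection around a body (shapes must match)."""

    def __init__(self, body: Module):
        super().__init__()
        self.body = body

    def forward(self, x):
        return self.body(x) + x

    def backward(self, grad_out):
        return self.body.backward(grad_out) + grad_out


class SqueezeExcite(Module):
    """Internal SE gate used inside MBConv-style blocks.

    The squeeze width is explicit (the backbones use family-specific rules),
    and the bottleneck activations are configurable: EfficientNet gates with
    SiLU/sigmoid, MobileNetV3 with ReLU/hard-sigmoid.  Implemented as 1x1
    projections with biases.
    """

    def __init__(self, channels: int, squeeze_channels: int,
                 act: str = "silu", gate: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.w1 = Parameter(rng.normal(0, np.sqrt(2.0 / channels),
                                       (squeeze_channels, channels)))
        self.b1 = Parameter(np.zeros(squeeze_channels, np.float32))
        self.w2 = Parameter(rng.normal(0, np.sqrt(2.0 / squeeze_channels),
                                       (channels, squeeze_channels)))
        self.b2 = Parameter(np.zeros(channels, np.float32))
        self.act = _ACTS[act]()
        self.gate = _ACTS[gate]()

    def forward(self, x):
        s = x.mean(axis=(2, 3))
        pre1 = s @ self.w1.data.T + self.b1.data
        h = self.act(pre1)
        pre2 = h @ self.w2.data.T + self.b2.data
        g = self.gate(pre2)
        self._cache = (x, s, h, g)
        return x * g[:, :, None, None]

    def backward(self, grad_out):
        x, s, h, g = self._cache
        n, c, hh, ww = x.shape
        dg = (grad_out * x).sum(axis=(2, 3))
        dpre2 = self.gate.backward(dg)
        self.w2.grad += dpre2.T @ h
        self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.w2.data
        dpre1 = self.act.backward(dh)
        self.w1.grad += dpre1.T @ s
        self.b1.grad += dpre1.sum(axis=0)
        ds = dpre1 @ self.w1.data
        gx = grad_out * g[:, :, None, None]
        gx += ds[:, :, None, None] / (hh * ww)
        return gx
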