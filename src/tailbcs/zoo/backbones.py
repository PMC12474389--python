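"""The six lightweight reference backbones, with swappable class heads.

Each builder reproduces the standard reference architecture of its family —
layer widths, kernel sizes, strides, squeeze-and-excitation placement and
classifier structure — so that trainable-parameter counts match the published
reference models exactly.  Only the final classification layer is resized to
the requested class count (for SqueezeNet that layer is a 1x1 convolution,
for every other family a linear layer).

Variant resolution: "SqueezeNet-1" is realized as SqueezeNet v1.1 and
"ShuffleNet" as ShuffleNetV2 x1.0; these are the variants whose parameter
counts (0.73 M and 1.26 M after the 5-class head swap) match the profiling
table this zoo mirrors.
"""

from __future__ import annotations

import numpy as np

from ..nn.core import Module, Sequential
from ..nn.layers import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Hardswish,
    Linear,
    MaxPool2d,
    ReLU,
)
from .base import ImageClassifier
from .blocks import Residual, SqueezeExcite, conv_bn_act

BACKBONES = (
    "efficientnet_b0",
    "mobilenet_v3_large",
    "mobilenet_v2",
    "mobilenet_v3_small",
    "squeezenet_1_1",
    "shufflenet_v2_x1_0",
)


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


# ---------------------------------------------------------------- EfficientNet
_EFFNET_B0_STAGES = [
    # expand, kernel, stride, in, out, repeats
    (1, 3, 1, 32, 16, 1),
    (6, 3, 2, 16, 24, 2),
    (6, 5, 2, 24, 40, 2),
    (6, 3, 2, 40, 80, 3),
    (6, 5, 1, 80, 112, 3),
    (6, 5, 2, 112, 192, 4),
    (6, 3, 1, 192, 320, 1),
]


def _mbconv(in_ch, out_ch, expand, kernel, stride, rng) -> Module:
    exp = in_ch * expand
    layers = []
    if expand != 1:
        layers.append(conv_bn_act(in_ch, exp, 1, act="silu", rng=rng))
    layers.append(conv_bn_act(exp, exp, kernel, stride=stride, groups=exp,
                              act="silu", rng=rng))
    layers.append(SqueezeExcite(exp, max(1, in_ch // 4), act="silu",
                                gate="sigmoid", rng=rng))
    layers.append(conv_bn_act(exp, out_ch, 1, act=None, rng=rng))
    body = Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return Residual(body)
    return body


def efficientnet_b0(num_classes: int = 5,
                    rng: np.random.Generator | None = None) -> ImageClassifier:
    rng = rng or np.random.default_rng(0)
    feats = [conv_bn_act(3, 32, 3, stride=2, act="silu", rng=rng)]
    for expand, k, s, c_in, c_out, reps in _EFFNET_B0_STAGES:
        for i in range(reps):
            feats.append(_mbconv(c_in if i == 0 else c_out, c_out, expand, k,
                                 s if i == 0 else 1, rng))
    feats.append(conv_bn_act(320, 1280, 1, act="silu", rng=rng))
    head = Sequential(GlobalAvgPool(), Dropout(0.2, rng=np.random.default_rng(rng.integers(2**31))),
                      Linear(1280, num_classes, rng=rng))
    return ImageClassifier(Sequential(*feats), head, 1280, name="efficientnet_b0")


# ----------------------------------------------------------------- MobileNetV2
_MBV2_STAGES = [  # expand t, out c, repeats n, stride s
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _inverted_residual_v2(in_ch, out_ch, expand, stride, rng) -> Module:
    exp = in_ch * expand
    layers = []
    if expand != 1:
        layers.append(conv_bn_act(in_ch, exp, 1, act="relu6", rng=rng))
    layers.append(conv_bn_act(exp, exp, 3, stride=stride, groups=exp,
                              act="relu6", rng=rng))
    layers.append(conv_bn_act(exp, out_ch, 1, act=None, rng=rng))
    body = Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return Residual(body)
    return body


def mobilenet_v2(num_classes: int = 5,
                 rng: np.random.Generator | None = None) -> ImageClassifier:
    rng = rng or np.random.default_rng(0)
    feats = [conv_bn_act(3, 32, 3, stride=2, act="relu6", rng=rng)]
    c_in = 32
    for t, c, n, s in _MBV2_STAGES:
        for i in range(n):
            feats.append(_inverted_residual_v2(c_in, c, t, s if i == 0 else 1, rng))
            c_in = c
    feats.append(conv_bn_act(320, 1280, 1, act="relu6", rng=rng))
    head = Sequential(GlobalAvgPool(), Dropout(0.2, rng=np.random.default_rng(rng.integers(2**31))),
                      Linear(1280, num_classes, rng=rng))
    return ImageClassifier(Sequential(*feats), head, 1280, name="mobilenet_v2")


# ----------------------------------------------------------------- MobileNetV3
# rows: in, kernel, expanded, out, use_se, activation, stride
_MBV3_LARGE = [
    (16, 3, 16, 16, False, "relu", 1),
    (16, 3, 64, 24, False, "relu", 2),
    (24, 3, 72, 24, False, "relu", 1),
    (24, 5, 72, 40, True, "relu", 2),
    (40, 5, 120, 40, True, "relu", 1),
    (40, 5, 120, 40, True, "relu", 1),
    (40, 3, 240, 80, False, "hardswish", 2),
    (80, 3, 200, 80, False, "hardswish", 1),
    (80, 3, 184, 80, False, "hardswish", 1),
    (80, 3, 184, 80, False, "hardswish", 1),
    (80, 3, 480, 112, True, "hardswish", 1),
    (112, 3, 672, 112, True, "hardswish", 1),
    (112, 5, 672, 160, True, "hardswish", 2),
    (160, 5, 960, 160, True, "hardswish", 1),
    (160, 5, 960, 160, True, "hardswish", 1),
]
_MBV3_SMALL = [
    (16, 3, 16, 16, True, "relu", 2),
    (16, 3, 72, 24, False, "relu", 2),
    (24, 3, 88, 24, False, "relu", 1),
    (24, 5, 96, 40, True, "hardswish", 2),
    (40, 5, 240, 40, True, "hardswish", 1),
    (40, 5, 240, 40, True, "hardswish", 1),
    (40, 5, 120, 48, True, "hardswish", 1),
    (48, 5, 144, 48, True, "hardswish", 1),
    (48, 5, 288, 96, True, "hardswish", 2),
    (96, 5, 576, 96, True, "hardswish", 1),
    (96, 5, 576, 96, True, "hardswish", 1),
]


def _inverted_residual_v3(row, rng) -> Module:
    in_ch, k, exp, out_ch, use_se, act, stride = row
    layers = []
    if exp != in_ch:
        layers.append(conv_bn_act(in_ch, exp, 1, act=act, rng=rng))
    layers.append(conv_bn_act(exp, exp, k, stride=stride, groups=exp, act=act, rng=rng))
    if use_se:
        layers.append(SqueezeExcite(exp, _make_divisible(exp // 4), act="relu",
                                    gate="hardsigmoid", rng=rng))
    layers.append(conv_bn_act(exp, out_ch, 1, act=None, rng=rng))
    body = Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return Residual(body)
    return body


def _mobilenet_v3(rows, last_conv_out, hidden, num_classes, name, rng) -> ImageClassifier:
    rng = rng or np.random.default_rng(0)
    feats = [conv_bn_act(3, 16, 3, stride=2, act="hardswish", rng=rng)]
    for row in rows:
        feats.append(_inverted_residual_v3(row, rng))
    feats.append(conv_bn_act(rows[-1][3], last_conv_out, 1, act="hardswish", rng=rng))
    head = Sequential(
        GlobalAvgPool(),
        Linear(last_conv_out, hidden, rng=rng),
        Hardswish(),
        Dropout(0.2, rng=np.random.default_rng(rng.integers(2**31))),
        Linear(hidden, num_classes, rng=rng),
    )
    return ImageClassifier(Sequential(*feats), head, last_conv_out, name=name)


def mobilenet_v3_large(num_classes: int = 5,
                       rng: np.random.Generator | None = None) -> ImageClassifier:
    return _mobilenet_v3(_MBV3_LARGE, 960, 1280, num_classes,
                         "mobilenet_v3_large", rng or np.random.default_rng(0))


def mobilenet_v3_small(num_classes: int = 5,
                       rng: np.random.Generator | None = None) -> ImageClassifier:
    return _mobilenet_v3(_MBV3_SMALL, 576, 1024, num_classes,
                         "mobilenet_v3_small", rng or np.random.default_rng(0))


# ------------------------------------------------------------------ SqueezeNet
class Fire(Module):
    def __init__(self, in_ch, squeeze, e1, e3, rng):
        super().__init__()
        self.squeeze = Conv2d(in_ch, squeeze, 1, bias=True, rng=rng)
        self.relu_s = ReLU()
        self.expand1 = Conv2d(squeeze, e1, 1, bias=True, rng=rng)
        self.relu1 = ReLU()
        self.expand3 = Conv2d(squeeze, e3, 3, padding=1, bias=True, rng=rng)
        self.relu3 = ReLU()
        self.e1 = e1

    def forward(self, x):
        s = self.relu_s(self.squeeze(x))
        a = self.relu1(self.expand1(s))
        b = self.relu3(self.expand3(s))
        return np.concatenate([a, b], axis=1)

    def backward(self, grad_out):
        ga, gb = grad_out[:, : self.e1], grad_out[:, self.e1 :]
        gs = self.expand1.backward(self.relu1.backward(ga))
        gs = gs + self.expand3.backward(self.relu3.backward(gb))
        return self.squeeze.backward(self.relu_s.backward(gs))


def squeezenet_1_1(num_classes: int = 5,
                   rng: np.random.Generator | None = None) -> ImageClassifier:
    rng = rng or np.random.default_rng(0)
    feats = Sequential(
        Conv2d(3, 64, 3, stride=2, bias=True, rng=rng),
        ReLU(),
        MaxPool2d(3, 2, ceil_mode=True),
        Fire(64, 16, 64, 64, rng),
        Fire(128, 16, 64, 64, rng),
        MaxPool2d(3, 2, ceil_mode=True),
        Fire(128, 32, 128, 128, rng),
        Fire(256, 32, 128, 128, rng),
        MaxPool2d(3, 2, ceil_mode=True),
        Fire(256, 48, 192, 192, rng),
        Fire(384, 48, 192, 192, rng),
        Fire(384, 64, 256, 256, rng),
        Fire(512, 64, 256, 256, rng),
    )
    head = Sequential(
        Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        Conv2d(512, num_classes, 1, bias=True, rng=rng),
        ReLU(),
        GlobalAvgPool(),
    )
    return ImageClassifier(feats, head, 512, name="squeezenet_1_1")


# ---------------------------------------------------------------- ShuffleNetV2
class ChannelShuffle(Module):
    def __init__(self, groups: int = 2):
        super().__init__()
        self.groups = groups

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.groups
        self._cache = (n, c, h, w)
        return np.ascontiguousarray(
            x.reshape(n, g, c // g, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)
        )

    def backward(self, grad_out):
        n, c, h, w = self._cache
        g = self.groups
        return np.ascontiguousarray(
            grad_out.reshape(n, c // g, g, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)
        )


class ShuffleUnit(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.stride = stride
        branch_ch = out_ch // 2
        if stride == 2:
            self.branch1 = Sequential(
                conv_bn_act(in_ch, in_ch, 3, stride=2, groups=in_ch, act=None, rng=rng),
                conv_bn_act(in_ch, branch_ch, 1, act="relu", rng=rng),
            )
            b2_in = in_ch
        else:
            object.__setattr__(self, "branch1", None)
            b2_in = in_ch // 2
        self.branch2 = Sequential(
            conv_bn_act(b2_in, branch_ch, 1, act="relu", rng=rng),
            conv_bn_act(branch_ch, branch_ch, 3, stride=stride,
                        groups=branch_ch, act=None, rng=rng),
            conv_bn_act(branch_ch, branch_ch, 1, act="relu", rng=rng),
        )
        self.shuffle = ChannelShuffle(2)
        self.branch_ch = branch_ch

    def forward(self, x):
        if self.stride == 2:
            a = self.branch1(x)
            b = self.branch2(x)
        else:
            half = x.shape[1] // 2
            a, b = x[:, :half], x[:, half:]
            b = self.branch2(b)
        return self.shuffle(np.concatenate([a, b], axis=1))

    def backward(self, grad_out):
        g = self.shuffle.backward(grad_out)
        ga, gb = g[:, : self.branch_ch], g[:, self.branch_ch :]
        if self.stride == 2:
            return self.branch1.backward(ga) + self.branch2.backward(gb)
        gb = self.branch2.backward(gb)
        return np.concatenate([ga, gb], axis=1)


def shufflenet_v2_x1_0(num_classes: int = 5,
                       rng: np.random.Generator | None = None) -> ImageClassifier:
    rng = rng or np.random.default_rng(0)
    feats = [
        conv_bn_act(3, 24, 3, stride=2, act="relu", rng=rng),
        MaxPool2d(3, 2, padding=1),
    ]
    c_in = 24
    for out_ch, repeats in ((116, 4), (232, 8), (464, 4)):
        for i in range(repeats):
            feats.append(ShuffleUnit(c_in if i == 0 else out_ch, out_ch,
                                     2 if i == 0 else 1, rng))
        c_in = out_ch
    feats.append(conv_bn_act(464, 1024, 1, act="relu", rng=rng))
    head = Sequential(GlobalAvgPool(), Linear(1024, num_classes, rng=rng))
    return ImageClassifier(Sequential(*feats), head, 1024, name="shufflenet_v2_x1_0")


# ---------------------------------------------------------------- tiny backbone
def tiny_cnn(num_classes: int = 5, width: int = 16,
             rng: np.random.Generator | None = None) -> ImageClassifier:
    """A three-stage small CNN for desk-scale experiments (synthetic corpora).

    Final feature width is ``4 * width`` (64 by default, divisible by the
    SE reduction ratio 16 so the composite attention variants also apply).
    """
    rng = rng or np.random.default_rng(0)
    feats = Sequential(
        conv_bn_act(3, width, 3, stride=2, act="relu", rng=rng),
        conv_bn_act(width, 2 * width, 3, stride=2, act="relu", rng=rng),
        conv_bn_act(2 * width, 4 * width, 3, stride=2, act="relu", rng=rng),
    )
    head = Sequential(GlobalAvgPool(), Linear(4 * width, num_classes, rng=rng))
    return ImageClassifier(feats, head, 4 * width, name="tiny")


_BUILDERS = {
    "efficientnet_b0": efficientnet_b0,
    "mobilenet_v3_large": mobilenet_v3_large,
    "mobilenet_v2": mobilenet_v2,
    "mobilenet_v3_small": mobilenet_v3_small,
    "squeezenet_1_1": squeezenet_1_1,
    "shufflenet_v2_x1_0": shufflenet_v2_x1_0,
    "tiny": tiny_cnn,
}


def build_backbone(name: str, num_classes: int = 5,
                   seed: int = 0) -> ImageClassifier:
    """Build a reference backbone with a ``num_classes``-way head."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown backbone {name!r}; choose from {sorted(_BUILDERS)}"
        )
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    return _BUILDERS[name](num_classes=num_classes, rng=np.random.default_rng(seed))
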