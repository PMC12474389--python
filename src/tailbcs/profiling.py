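"""Model profiling: parameter counts, serialized size, approximate MACs, latency.

Conventions: parameters are trainable weights and biases only (normalization
running statistics and other buffers are excluded); serialized size assumes
float32 storage, ``params * 4 bytes / 2**20`` binary MiB.  The MAC count sums
``H_out * W_out * K_h * K_w * C_in * C_out / groups`` over convolutions plus
``in * out`` over linear layers; it is convention-dependent and reported as
informational only, as is wall-clock latency.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .nn.core import Module
from .nn.layers import Conv2d, Linear

__all__ = [
    "ProfileReport",
    "count_parameters",
    "model_size_mib",
    "count_flops",
    "latency_profile",
    "profile_model",
]


@dataclass
class ProfileReport:
    trainable_params: int
    params_millions: float
    flops_millions: float
    size_mib: float
    latency_ms: float

    def as_dict(self) -> dict:
        return {
            "trainable_params": self.trainable_params,
            "params_millions": self.params_millions,
            "flops_millions": self.flops_millions,
            "size_mib": self.size_mib,
            "latency_ms": self.latency_ms,
        }


def count_parameters(model: Module) -> int:
    """Number of trainable weights and biases."""
    return sum(p.size for p in model.parameters())


def model_size_mib(model: Module) -> float:
    """Serialized float32 size in binary MiB, rounded to 2 decimals."""
    return round(count_parameters(model) * 4 / 2**20, 2)


def count_flops(model: Module, input_size: int = 224) -> int:
    """Approximate multiply-accumulate count of one forward pass.

    Runs a forward pass on a zero batch to record per-layer output shapes,
    then sums the conv/linear contraction sizes.
    """
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, input_size, input_size), np.float32)
    model(x)
    model.train(was_training)
    total = 0
    for m in model.modules():
        if isinstance(m, Conv2d) and m.last_output_shape is not None:
            _, _, ho, wo = m.last_output_shape
            k = m.kernel_size
            total += ho * wo * k * k * m.in_channels * m.out_channels // m.groups
        elif isinstance(m, Linear):
            total += m.in_features * m.out_features
    return total


def latency_profile(model: Module, input_size: int = 224, n_repeats: int = 10,
                    n_warmup: int = 2) -> float:
    """Median single-image forward wall time in milliseconds (informational)."""
    model.eval()
    x = np.zeros((1, 3, input_size, input_size), np.float32)
    for _ in range(n_warmup):
        model(x)
    times = []
    for _ in range(max(n_repeats, 1)):
        t0 = time.perf_counter()
        model(x)
        times.append((time.perf_counter() - t0) * 1e3)
    return float(np.median(times))


def profile_model(model: Module, input_size: int = 224, with_latency: bool = True,
                  with_flops: bool = True) -> ProfileReport:
    n = count_parameters(model)
    return ProfileReport(
        trainable_params=n,
        params_millions=round(n / 1e6, 2),
        flops_millions=round(count_flops(model, input_size) / 1e6, 2) if with_flops else float("nan"),
        size_mib=round(n * 4 / 2**20, 2),
        latency_ms=latency_profile(model, input_size) if with_latency else float("nan"),
    )
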