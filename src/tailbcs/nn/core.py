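"""Minimal neural-network core: parameters, modules, sequential containers.

Every module implements ``forward`` and ``backward``.  ``forward`` caches
whatever the matching ``backward`` call needs; ``backward`` consumes the most
recent cache, accumulates gradients into ``Parameter.grad`` and returns the
gradient with respect to its input.  All arrays are float32 NCHW.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Parameter", "Module", "Sequential"]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class; tracks sub-modules and parameters in definition order."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Parameter):
            self._params[name] = value
        object.__setattr__(self, name, value)

    # -- introspection -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- state dict ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self.named_buffers():
            state[name] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data[...] = value
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield (f"{prefix}{name}", getattr(self, name))
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix=f"{prefix}{name}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        if not hasattr(self, "_buffer_names"):
            object.__setattr__(self, "_buffer_names", [])
        self._buffer_names.append(name)
        object.__setattr__(self, name, value)

    # -- computation ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self._modules[str(i)] = layer

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, idx: int) -> Module:
        return self.layers[idx]

    def append(self, layer: Module) -> None:
        self._modules[str(len(self.layers))] = layer
        self.layers.append(layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def forward_upto(self, x: np.ndarray, idx: int) -> np.ndarray:
        """Run layers 0..idx inclusive (used to capture intermediate maps)."""
        for layer in self.layers[: idx + 1]:
            x = layer(x)
        return x

    def forward_from(self, x: np.ndarray, idx: int) -> np.ndarray:
        """Run layers idx+1..end."""
        for layer in self.layers[idx + 1 :]:
            x = layer(x)
        return x

    def backward_to(self, grad_out: np.ndarray, idx: int) -> np.ndarray:
        """Backpropagate through layers end..idx+1, returning the gradient
        at the output of layer ``idx``."""
        for layer in reversed(self.layers[idx + 1 :]):
            grad_out = layer.backward(grad_out)
        return grad_out
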