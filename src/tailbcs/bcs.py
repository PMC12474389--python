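"""The five-point body-condition scale and its class-index mapping.

Scores run from lean to fat in 0.25 steps; class index 0 is the leanest
animal (deepest tail-root depression), index 4 the fattest (flattest).
"""

from __future__ import annotations

import numpy as np

BCS_VALUES: tuple[float, ...] = (3.25, 3.50, 3.75, 4.00, 4.25)
NUM_CLASSES = len(BCS_VALUES)


def value_to_index(value: float) -> int:
    """Map a BCS value to its class index; raise if not on the scale."""
    for i, v in enumerate(BCS_VALUES):
        if abs(float(value) - v) < 1e-9:
            return i
    raise ValueError(f"{value!r} is not a legal BCS value {BCS_VALUES}")


def index_to_value(index: int) -> float:
    if not 0 <= int(index) < NUM_CLASSES:
        raise ValueError(f"class index must lie in 0..{NUM_CLASSES - 1}")
    return BCS_VALUES[int(index)]


def values_to_indices(values) -> np.ndarray:
    return np.array([value_to_index(v) for v in np.asarray(values).ravel()])


def indices_to_values(indices) -> np.ndarray:
    return np.array([index_to_value(i) for i in np.asarray(indices).ravel()])
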