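"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as clinical reports conventionally do.

    numpy/python round() use banker's rounding; printed tables in the
    radiology literature round 0.5 up, so comparisons against printed
    integers need this variant.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def as_unit_vector(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector cannot be normalised")
    return v / n
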