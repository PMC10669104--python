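"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Banker's rounding (Python's built-in) would turn 0.125 into 0.12; the
    tabular conventions used throughout this package expect 0.13.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_gray_float(image: np.ndarray) -> np.ndarray:
    """Return a 2-D float64 view of an intensity image on the 0–255 scale.

    Accepts uint8 arrays (returned as float), or real arrays in [0, 1]
    (rescaled by 255).
    """
    a = np.asarray(image)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D intensity image, got shape {a.shape}")
    a = a.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.floating) and a.size and a.max() <= 1.0:
        a = a * 255.0
    return a
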