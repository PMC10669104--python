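"""Focus quality measures for frame sequences.

Two classical sharpness scores:

* SDF — sum of absolute grayscale differences between horizontal and
  vertical neighbours (SMD family), normalised by the pixel count M·N;
* TDF — Tenengrad: squared Sobel gradient magnitude averaged over M·N.

Both are 0 on constant images, invariant to a constant intensity offset,
and decrease as an image is blurred, so a per-sequence normalised series
flags defocused stretches of a video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._utils import as_gray_float

SOBEL_X = np.array([[-1., 0., 1.],
                    [-2., 0., 2.],
                    [-1., 0., 1.]])
SOBEL_Y = SOBEL_X.T


def sdf(image: np.ndarray) -> float:
    """Sum of absolute neighbour differences over M·N.

    Only in-bounds neighbour pairs contribute; the divisor is the full
    pixel count M·N.
    """
    a = as_gray_float(image)
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    total = np.abs(np.diff(a, axis=1)).sum() + np.abs(np.diff(a, axis=0)).sum()
    return float(total / a.size)


def tdf(image: np.ndarray, literal_sum: bool = False) -> float:
    """Tenengrad focus measure: mean squared Sobel gradient magnitude.

    ``S = sqrt((Gx∗I)² + (Gy∗I)²)`` is evaluated with the 3×3 Sobel kernels,
    squared, summed over the interior (border pixels, where the kernel
    overhangs, are excluded) and divided by M·N.  ``literal_sum=True``
    switches to the plain-sum variant ``S = Gx∗I + Gy∗I``.
    """
    a = as_gray_float(image)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the Sobel kernel")
    gx = ndi.correlate(a, SOBEL_X, mode="constant")[1:-1, 1:-1]
    gy = ndi.correlate(a, SOBEL_Y, mode="constant")[1:-1, 1:-1]
    s = gx + gy if literal_sum else np.hypot(gx, gy)
    return float((s ** 2).sum() / a.size)


@dataclass
class SharpnessSeries:
    """Per-frame raw and max-normalised SDF/TDF values."""

    sdf_raw: np.ndarray
    tdf_raw: np.ndarray
    sdf_norm: np.ndarray
    tdf_norm: np.ndarray


def _normalize(raw: np.ndarray) -> np.ndarray:
    m = raw.max() if raw.size else 0.0
    return raw / m if m > 0 else np.zeros_like(raw)


def score_sequence(frames) -> SharpnessSeries:
    """SDF and TDF for every frame, plus series normalised by their maxima.

    An all-constant sequence (raw maxima 0) normalises to all zeros.
    """
    frame_list = list(frames)
    if not frame_list:
        raise ValueError("empty sequence")
    sdf_raw = np.array([sdf(f) for f in frame_list])
    tdf_raw = np.array([tdf(f) for f in frame_list])
    return SharpnessSeries(sdf_raw, tdf_raw, _normalize(sdf_raw), _normalize(tdf_raw))
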