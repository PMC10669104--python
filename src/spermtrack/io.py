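"""Calibrated frame-sequence input/output.

Everything downstream consumes a :class:`FrameSequence`: an ordered stack of
same-sized grayscale frames plus a :class:`Calibration` giving the physical
pixel size (µm/px) and frame rate (fps).  Internally the package works in
pixels and frames; physical units enter only when kinematics are computed.

Coordinates follow the raster convention: (row, col), 0-based, origin at the
top-left; centroids are real-valued (row, col) pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

# ITU-R BT.601 luma weights used for colour → grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of the imaging system.

    Parameters
    ----------
    um_per_px : float
        Micrometres spanned by one pixel (> 0).
    fps : float
        Frames per second of the video (> 0).
    """

    um_per_px: float = 0.074
    fps: float = 29.80

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be strictly positive")
        if not self.fps > 0:
            raise ValueError("fps must be strictly positive")


class FrameSequence:
    """Ordered grayscale frames with calibration metadata.

    Frames are stored as a single ``(n, height, width)`` uint8 array.  Frame
    index is 0-based; the timestamp of frame *i* is ``i / fps`` seconds.
    """

    def __init__(self, frames: Iterable[np.ndarray] | np.ndarray, calibration: Calibration):
        if isinstance(frames, np.ndarray) and frames.ndim == 3:
            stack = frames
        else:
            frame_list = [np.asarray(f) for f in frames]
            if not frame_list:
                raise ValueError("empty sequence")
            shapes = {f.shape for f in frame_list}
            if len(shapes) != 1:
                raise ValueError(f"inconsistent frame sizes: {sorted(shapes)}")
            stack = np.stack(frame_list)
        if stack.size == 0 or stack.shape[0] == 0:
            raise ValueError("empty sequence")
        if stack.ndim != 3:
            raise ValueError("frames must be 2-D intensity images")
        self.data = _to_uint8(stack)
        self.calibration = calibration

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def __iter__(self):
        return iter(self.data)

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds, ``index / fps``."""
        return np.arange(len(self)) / self.calibration.fps


def _to_uint8(stack: np.ndarray) -> np.ndarray:
    if stack.dtype == np.uint8:
        return stack
    a = stack.astype(np.float64)
    if a.size and a.max() <= 1.0 and a.min() >= 0.0:
        a = a * 255.0
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to 8-bit grayscale using BT.601 luma weights.

    Already-gray input passes through unchanged (idempotent); an alpha
    channel, if present, is ignored.
    """
    a = np.asarray(image)
    if a.ndim == 2:
        return _to_uint8(a[None])[0]
    if a.ndim == 3 and a.shape[2] in (3, 4):
        rgb = _to_uint8(np.moveaxis(a[:, :, :3], 2, 0))
        gray = np.tensordot(rgb.astype(np.float64), LUMA_WEIGHTS, axes=(0, 0))
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot interpret shape {a.shape} as an image")


def _numeric_key(path: Path):
    """Sort key that orders frame_2 before frame_10."""
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def load_frames(path: str | Path, calibration: Calibration | None = None) -> FrameSequence:
    """Read a video container or a directory of numbered images.

    Colour input is converted to grayscale via the 0.299/0.587/0.114 luma
    weights.  All frames must share one size.

    Raises
    ------
    ValueError
        If the path holds no readable frames or frame sizes differ.
    """
    calibration = calibration or Calibration()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"empty sequence: no image files in {p}")
        frames = [to_grayscale(iio.imread(f)) for f in files]
    else:
        try:
            frames = [to_grayscale(f) for f in iio.imiter(p)]
        except Exception as exc:  # codec/plugin failures surface uniformly
            raise ValueError(f"could not decode video {p}: {exc}") from exc
        if not frames:
            raise ValueError(f"empty sequence: no frames decoded from {p}")
    return FrameSequence(frames, calibration)


def write_frames(seq: FrameSequence | Sequence[np.ndarray], out_dir: str | Path,
                 prefix: str = "frame", fmt: str = "png") -> list[Path]:
    """Write frames as numbered lossless images; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = seq.data if isinstance(seq, FrameSequence) else [np.asarray(f) for f in seq]
    n = len(frames)
    width = max(4, len(str(n)))
    paths = []
    for i, frame in enumerate(frames):
        fp = out / f"{prefix}_{i:0{width}d}.{fmt}"
        iio.imwrite(fp, _to_uint8(np.asarray(frame)[None])[0])
        paths.append(fp)
    return paths
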