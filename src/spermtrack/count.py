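"""Static sperm counting in a single frame.

The count includes both moving and stationary cells, so it runs on one frame
at a time without any motion model: grayscale → Otsu threshold → hole filling
→ morphological opening (to split touching cells) → small-object removal
(white blood cells, dust) → 8-connected component count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from ._utils import as_gray_float

#: Impurity-area threshold (px) and the pixel size (µm/px) it was tuned at.
REFERENCE_MIN_AREA = 70.0
REFERENCE_UM_PER_PX = 0.074

#: Smallest usable area threshold: below a few pixels nothing can be resolved,
#: whatever the calibration says.
MIN_RESOLVABLE_AREA = 4.0


@dataclass(frozen=True)
class Detection:
    """One segmented object in one frame."""

    frame_index: int
    centroid: tuple[float, float]  # (row, col), px
    area: int                      # px
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open

    def __post_init__(self):
        r, c = self.centroid
        r0, c0, r1, c1 = self.bbox
        if not (r0 - 0.5 <= r <= r1 + 0.5 and c0 - 0.5 <= c <= c1 + 0.5):
            raise ValueError("centroid outside bounding box")


@dataclass
class CountResult:
    count: int
    detections: list[Detection] = field(default_factory=list)
    otsu_level: float = 0.0
    mask: np.ndarray | None = None


def scaled_min_area(um_per_px: float, base_area: float = REFERENCE_MIN_AREA,
                    base_um_per_px: float = REFERENCE_UM_PER_PX) -> float:
    """Rescale an area threshold (px²-denominated) to another pixel size.

    Area scales with the square of the linear magnification ratio; the result
    is floored at :data:`MIN_RESOLVABLE_AREA` because sub-resolution area
    thresholds cannot reject single-pixel noise.
    """
    return max(MIN_RESOLVABLE_AREA, base_area * (base_um_per_px / um_per_px) ** 2)


def otsu_threshold(gray: np.ndarray) -> float:
    """Between-class-variance-maximising threshold, returned as level in [0, 1].

    The search runs over the 256 integer thresholds of an 8-bit histogram
    (float input in [0, 1] is rescaled).  If several thresholds tie for the
    maximum between-class variance, the midpoint of the tying plateau is
    returned — a deterministic, symmetric convention.

    Raises
    ------
    ValueError
        If the image has a single intensity value ("degenerate histogram").
    """
    a = as_gray_float(gray)
    hist, _ = np.histogram(a, bins=256, range=(-0.5, 255.5))
    p = hist.astype(np.float64) / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # weight of class {0..t}
    m = np.cumsum(p * levels)              # first moment of class {0..t}
    mt = m[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)            # both classes non-empty
    if not valid.any():
        raise ValueError("degenerate histogram: constant image")
    sigma_b = np.full(256, -np.inf)
    sigma_b[valid] = (mt * w0[valid] - m[valid]) ** 2 / (w0[valid] * w1[valid])
    best = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= best - 1e-12 * max(best, 1.0))
    t = (plateau[0] + plateau[-1]) / 2.0
    return t / 255.0


def binarize(gray: np.ndarray, level: float) -> np.ndarray:
    """Boolean mask, True where intensity exceeds ``level``·255 (bright objects)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    return as_gray_float(gray) > level * 255.0


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set enclosed background regions to foreground."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def morph_open(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary opening (erosion then dilation) with a disk structuring element.

    ``radius=0`` is the identity.  Opening detaches thin bridges between
    touching cells and shaves single-pixel protrusions.
    """
    m = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return m.copy()
    return ndi.binary_opening(m, structure=morphology.disk(radius))


def morph_close(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disk structuring element.

    Closing bridges small gaps inside a fragmented blob — e.g. the split
    between the leading and trailing edges of a moving cell in a
    background-subtraction mask.
    """
    m = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return m.copy()
    return ndi.binary_closing(m, structure=morphology.disk(radius))


def remove_small(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Drop 8-connected components with area strictly below ``min_area`` px."""
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    m = np.asarray(mask, dtype=bool)
    if min_area <= 1:
        return m.copy()
    labels = measure.label(m, connectivity=2)
    if labels.max() == 0:
        return m.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def label_detections(mask: np.ndarray, frame_index: int = 0) -> list[Detection]:
    """8-connected components of a mask as Detections, sorted by (row, col)."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    dets = []
    for region in measure.regionprops(labels):
        r, c = region.centroid
        dets.append(Detection(frame_index=frame_index, centroid=(float(r), float(c)),
                              area=int(region.area), bbox=tuple(region.bbox)))
    dets.sort(key=lambda d: d.centroid)
    return dets


def declump_detections(mask: np.ndarray, frame_index: int = 0,
                       factor: float = 1.6, max_split: int = 6) -> list[Detection]:
    """Label a mask, splitting components that hold several adhered cells.

    Morphological opening cannot separate cells whose bodies genuinely
    overlap, so any component whose area exceeds ``factor`` times the
    median component area (a robust single-cell size estimate when most
    cells are isolated) is divided into ``round(area / median)`` cells by
    k-means on its pixel coordinates.  Deterministic given the mask.

    A component more than ``max_split`` times the median is a segmentation
    failure (e.g. a collapsed threshold), not a clump of cells, and is kept
    whole.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = measure.regionprops(labels)
    if not regions:
        return []
    median_area = float(np.median([r.area for r in regions]))
    dets: list[Detection] = []
    for region in regions:
        k = int(round(region.area / median_area)) if region.area > factor * median_area else 1
        if k <= 1 or k > max_split:
            r, c = region.centroid
            dets.append(Detection(frame_index=frame_index, centroid=(float(r), float(c)),
                                  area=int(region.area), bbox=tuple(region.bbox)))
            continue
        coords = region.coords.astype(float)
        from scipy.cluster.vq import kmeans2

        _, assign = kmeans2(coords, k, minit="++", seed=1234, iter=20)
        for j in range(k):
            sub = coords[assign == j]
            if len(sub) == 0:
                continue
            r, c = sub.mean(axis=0)
            r0, c0 = sub.min(axis=0).astype(int)
            r1, c1 = sub.max(axis=0).astype(int) + 1
            dets.append(Detection(frame_index=frame_index, centroid=(float(r), float(c)),
                                  area=int(len(sub)), bbox=(int(r0), int(c0), int(r1), int(c1))))
    dets.sort(key=lambda d: d.centroid)
    return dets


def count_sperm(frame: np.ndarray, *, level: float | None = None, open_radius: int = 1,
                min_area: float = REFERENCE_MIN_AREA, polarity: str = "bright",
                declump: bool = True, frame_index: int = 0) -> CountResult:
    """Count sperm-sized objects in one frame.

    Pipeline order is fixed: binarize (Otsu unless ``level`` overrides) →
    fill holes → open → remove small → 8-connected count, optionally with
    area-based declumping of components holding several adhered cells.

    Parameters
    ----------
    level : float, optional
        Fixed normalized threshold; ``None`` selects it by Otsu's method.
    open_radius : int
        Disk radius of the opening used to split touching cells.
    min_area : float
        Impurity-removal area threshold in pixels (70 px at 0.074 µm/px;
        use :func:`scaled_min_area` for other calibrations).
    polarity : {"bright", "dark"}
        "bright" segments bright objects on a dark background; "dark"
        inverts the frame first.
    declump : bool
        Split components much larger than the typical single-cell area
        (see :func:`declump_detections`).
    """
    gray = as_gray_float(frame)
    if polarity == "dark":
        gray = 255.0 - gray
    elif polarity != "bright":
        raise ValueError("polarity must be 'bright' or 'dark'")
    lvl = otsu_threshold(gray) if level is None else float(level)
    mask = binarize(gray, lvl)
    mask = fill_holes(mask)
    mask = morph_open(mask, open_radius)
    mask = remove_small(mask, min_area)
    if declump:
        dets = declump_detections(mask, frame_index)
    else:
        dets = label_detections(mask, frame_index)
    return CountResult(count=len(dets), detections=dets, otsu_level=lvl, mask=mask)
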