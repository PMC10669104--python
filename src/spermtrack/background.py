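"""Adaptive per-pixel Gaussian-mixture background subtraction.

Each pixel's intensity history is modelled as a mixture of K scalar
Gaussians (weight ω, mean µ, variance σ²) updated online in the
Stauffer–Grimson fashion.  Components are ranked by ω/σ; the smallest prefix
of the ranking whose cumulative weight exceeds the background ratio ξ is
declared background.  A pixel is foreground when its current value matches no
component, or matches one outside the background set — which is exactly what
a swimming sperm cell does to the pixels it crosses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_gray_float
from .count import (MIN_RESOLVABLE_AREA, Detection, label_detections, morph_close,
                    remove_small, scaled_min_area)

#: Motion-blob area threshold (px) at the reference pixel size (0.074 µm/px).
REFERENCE_MIN_BLOB_AREA = 40.0


@dataclass(frozen=True)
class MixtureParams:
    """Operating point of the background mixture.

    Defaults are the standard adaptive-mixture settings; all are exposed
    because microscopy contrast varies between set-ups.

    Attributes
    ----------
    n_components : int
        K, Gaussians per pixel.
    alpha : float
        Learning rate for weights and matched-component moments.
    match_threshold : float
        λ: a value matches a component when |X − µ| ≤ λσ.
    background_ratio : float
        ξ: cumulative-weight fraction declared background.
    var_init : float
        Variance assigned to newly created components ((15 gray levels)²).
    var_min : float
        Variance floor ((4 gray levels)²), a numerical guard.
    init_weight : float
        Weight given to a replacement component before renormalisation.
    warmup : bool
        Use the 1/t learning-rate schedule while the model is young, so the
        first frames (including any object learned into the model at
        initialisation) are absorbed quickly.
    """

    n_components: int = 3
    alpha: float = 0.01
    match_threshold: float = 2.5
    background_ratio: float = 0.7
    var_init: float = 15.0 ** 2
    var_min: float = 4.0 ** 2
    init_weight: float = 0.05
    warmup: bool = True

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.background_ratio < 1:
            raise ValueError("background_ratio must lie in (0, 1)")


class BackgroundModel:
    """Online per-pixel Gaussian mixture; see module docstring.

    Build with :func:`init_background`, then call
    :func:`update_and_classify` once per subsequent frame.
    """

    def __init__(self, first_frame: np.ndarray, params: MixtureParams | None = None):
        self.params = params or MixtureParams()
        frame = as_gray_float(first_frame)
        k, (h, w) = self.params.n_components, frame.shape
        self.shape = (h, w)
        self.weights = np.zeros((k, h, w))
        self.means = np.zeros((k, h, w))
        self.variances = np.full((k, h, w), self.params.var_init)
        # First component adopts the first frame with full weight.
        self.weights[0] = 1.0
        self.means[0] = frame
        self.n_seen = 1

    # -- internals ---------------------------------------------------------

    def _sorted_order(self) -> np.ndarray:
        rank = self.weights / np.sqrt(self.variances)
        return np.argsort(-rank, axis=0, kind="stable")

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Classify ``frame`` against the current model, then update it.

        Returns the boolean foreground mask.  Classification uses the model
        state *before* the update, so a sudden change is flagged the frame it
        happens.
        """
        p = self.params
        x = as_gray_float(frame)
        if x.shape != self.shape:
            raise ValueError(f"frame shape {x.shape} != model shape {self.shape}")
        self.n_seen += 1
        alpha = max(p.alpha, 1.0 / self.n_seen) if p.warmup else p.alpha

        order = self._sorted_order()
        w_s = np.take_along_axis(self.weights, order, axis=0)
        mu_s = np.take_along_axis(self.means, order, axis=0)
        sd_s = np.sqrt(np.take_along_axis(self.variances, order, axis=0))

        matched_s = np.abs(x[None] - mu_s) <= p.match_threshold * sd_s
        matched_s &= w_s > 0  # zero-weight slots are vacant, not matchable
        any_match = matched_s.any(axis=0)
        first_s = matched_s.argmax(axis=0)

        # Background set: smallest prefix of the ranking whose cumulative
        # weight exceeds ξ ⇒ a sorted slot is background iff the weight
        # accumulated before it has not yet exceeded ξ.
        cum_excl = np.cumsum(w_s, axis=0) - w_s
        bg_s = cum_excl <= p.background_ratio
        matched_bg = np.take_along_axis(bg_s, first_s[None], axis=0)[0]
        foreground = ~any_match | ~matched_bg

        # --- update -------------------------------------------------------
        comp = np.take_along_axis(order, first_s[None], axis=0)[0]
        k_index = np.arange(p.n_components)[:, None, None]
        is_matched = (comp[None] == k_index) & any_match[None]

        self.weights = (1.0 - alpha) * self.weights + alpha * is_matched
        rho = alpha
        mu_new = (1.0 - rho) * self.means + rho * x[None]
        var_new = (1.0 - rho) * self.variances + rho * (x[None] - mu_new) ** 2
        self.means = np.where(is_matched, mu_new, self.means)
        self.variances = np.where(is_matched, var_new, self.variances)

        # No match anywhere: recycle the lowest-ranked component.
        weakest = order[-1]
        replace = (weakest[None] == k_index) & (~any_match)[None]
        self.means = np.where(replace, x[None], self.means)
        self.variances = np.where(replace, p.var_init, self.variances)
        self.weights = np.where(replace, p.init_weight, self.weights)

        np.maximum(self.variances, p.var_min, out=self.variances)
        self.weights /= self.weights.sum(axis=0, keepdims=True)
        return foreground


def init_background(first_frame: np.ndarray, params: MixtureParams | None = None) -> BackgroundModel:
    """Initialise the mixture from the first frame (one full-weight component per pixel)."""
    return BackgroundModel(first_frame, params)


def update_and_classify(model: BackgroundModel, frame: np.ndarray) -> tuple[BackgroundModel, np.ndarray]:
    """Functional wrapper around :meth:`BackgroundModel.apply`."""
    mask = model.apply(frame)
    return model, mask


def extract_detections(mask: np.ndarray, frame_index: int,
                       min_blob_area: float = REFERENCE_MIN_BLOB_AREA,
                       close_radius: int = 0) -> list[Detection]:
    """Turn a foreground mask into centroid detections.

    8-connected components with area ≥ ``min_blob_area`` become
    :class:`~spermtrack.count.Detection` objects with intensity-unweighted
    centroids, sorted by (row, col).  ``close_radius > 0`` first applies a
    binary closing, which re-joins a cell whose motion mask split into a
    leading and a trailing crescent (the still-covered interior matches the
    background model for the first frames after initialisation).
    """
    m = np.asarray(mask, dtype=bool)
    if close_radius > 0:
        # Drop sub-resolution speckle first so closing cannot weld isolated
        # noise pixels into fake blobs, then bridge the real fragments.
        m = morph_close(remove_small(m, MIN_RESOLVABLE_AREA), close_radius)
    cleaned = remove_small(m, min_blob_area)
    return label_detections(cleaned, frame_index)


def scaled_min_blob_area(um_per_px: float) -> float:
    """Motion-blob area threshold rescaled from the reference calibration."""
    return scaled_min_area(um_per_px, base_area=REFERENCE_MIN_BLOB_AREA)
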