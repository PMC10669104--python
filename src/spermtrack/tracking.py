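"""Multi-object tracking of swimming sperm.

Each cell is tracked with a constant-velocity Kalman filter over state
(row, col, v_row, v_col) in pixels and pixels/frame, observing (row, col).
Frame-to-frame association is the minimum-total-Euclidean-cost one-to-one
assignment (Hungarian algorithm) with a distance gate; unmatched tracks
coast on prediction and are deleted after ``max_age`` consecutive misses,
unmatched detections spawn new tracks.

Tracking quality is scored by the tracking rate Rt = 100·Ft/Fw, the
percentage of an object's presence frames during which a single track
identity followed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from ._utils import round_half_up
from .background import BackgroundModel, MixtureParams, extract_detections, scaled_min_blob_area
from .count import Detection, count_sperm, scaled_min_area

# Constant-velocity transition and position observation, dt = 1 frame.
A_CV = np.array([[1., 0., 1., 0.],
                 [0., 1., 0., 1.],
                 [0., 0., 1., 0.],
                 [0., 0., 0., 1.]])
H_POS = np.array([[1., 0., 0., 0.],
                  [0., 1., 0., 0.]])


@dataclass
class KalmanState:
    """State estimate x̂ = (row, col, v_row, v_col) and covariance P."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(4)
        self.P = np.asarray(self.P, dtype=float).reshape(4, 4)

    @property
    def position(self) -> np.ndarray:
        return self.x[:2]


@dataclass(frozen=True)
class TrackerParams:
    """Association and lifecycle settings.

    gate is in working-resolution pixels: it bounds per-frame displacement
    plus prediction error rather than a physical object size, so it is not
    rescaled with calibration by default.
    """

    gate: float = 50.0
    max_age: int = 5
    min_hits: int = 1
    process_noise: float = 0.01      # Q = process_noise · I₄
    measurement_noise: float = 1.0   # R = measurement_noise · I₂
    p0_pos: float = 1.0
    p0_vel: float = 10.0

    @property
    def Q(self) -> np.ndarray:
        return self.process_noise * np.eye(4)

    @property
    def R(self) -> np.ndarray:
        return self.measurement_noise * np.eye(2)

    @property
    def P0(self) -> np.ndarray:
        return np.diag([self.p0_pos, self.p0_pos, self.p0_vel, self.p0_vel])


def kalman_predict(state: KalmanState, A: np.ndarray = A_CV,
                   Q: np.ndarray | None = None) -> KalmanState:
    """Time update: x̂⁻ = A x̂, P⁻ = A P Aᵀ + Q."""
    Q = np.zeros((4, 4)) if Q is None else Q
    return KalmanState(A @ state.x, A @ state.P @ A.T + Q)


def kalman_update(state: KalmanState, z: np.ndarray, H: np.ndarray = H_POS,
                  R: np.ndarray | None = None) -> KalmanState:
    """Measurement update with gain K = P⁻Hᵀ(HP⁻Hᵀ + R)⁻¹.

    Raises
    ------
    np.linalg.LinAlgError
        If the innovation covariance HP⁻Hᵀ + R is singular (degenerate
        R and P).
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    m = H.shape[0]
    R = np.zeros((m, m)) if R is None else R
    S = H @ state.P @ H.T + R
    if np.linalg.matrix_rank(S) < m:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = state.P @ H.T @ np.linalg.inv(S)
    x = state.x + K @ (z - H @ state.x)
    P = (np.eye(len(state.x)) - K @ H) @ state.P
    # Symmetrise to keep P numerically PSD over long runs.
    return KalmanState(x, (P + P.T) / 2.0)


def assign(predicted: list[tuple[float, float]] | np.ndarray,
           detected: list[tuple[float, float]] | np.ndarray,
           gate: float) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Gated minimum-cost one-to-one assignment of predictions to detections.

    Returns (matches, unmatched_prediction_indices, unmatched_detection_indices);
    a globally optimal pair whose distance exceeds ``gate`` is demoted to
    unmatched on both sides.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    pred = np.atleast_2d(np.asarray(predicted, dtype=float)) if len(predicted) else np.empty((0, 2))
    det = np.atleast_2d(np.asarray(detected, dtype=float)) if len(detected) else np.empty((0, 2))
    if pred.shape[0] == 0 or det.shape[0] == 0:
        return [], list(range(pred.shape[0])), list(range(det.shape[0]))
    cost = cdist(pred, det)
    rows, cols = linear_sum_assignment(cost)
    matches, um_t, um_d = [], set(range(pred.shape[0])), set(range(det.shape[0]))
    for i, j in zip(rows, cols):
        if cost[i, j] <= gate:
            matches.append((int(i), int(j)))
            um_t.discard(int(i))
            um_d.discard(int(j))
    return matches, sorted(um_t), sorted(um_d)


@dataclass
class Track:
    """One sperm identity and its observation history."""

    id: int
    kalman: KalmanState
    centroids: list[tuple[int, float, float]] = field(default_factory=list)  # (frame, row, col)
    appear_frame: int = 0
    last_seen_frame: int = 0
    misses: int = 0
    hits: int = 0
    status: str = "active"
    mean_area: float = 0.0

    @property
    def frames_tracked(self) -> int:
        """Ft: number of frames with a recorded (matched) centroid."""
        return len(self.centroids)


class Tracker:
    """Stateful frame-by-frame tracker; IDs increase monotonically and are
    never reused within a run."""

    def __init__(self, params: TrackerParams | None = None):
        self.params = params or TrackerParams()
        self.tracks: list[Track] = []
        self._next_id = 1

    def _new_track(self, det: Detection, frame_index: int) -> Track:
        r, c = det.centroid
        state = KalmanState(np.array([r, c, 0.0, 0.0]), self.params.P0.copy())
        t = Track(id=self._next_id, kalman=state, appear_frame=frame_index,
                  last_seen_frame=frame_index, hits=1, mean_area=det.area)
        t.centroids.append((frame_index, r, c))
        self._next_id += 1
        return t

    def step(self, detections: list[Detection], frame_index: int) -> list[Track]:
        """Advance all active tracks by one frame of detections."""
        p = self.params
        active = [t for t in self.tracks if t.status == "active"]
        for t in active:
            t.kalman = kalman_predict(t.kalman, A_CV, p.Q)
        preds = [tuple(t.kalman.position) for t in active]
        dets = [d.centroid for d in detections]
        matches, um_t, um_d = assign(preds, dets, p.gate)
        for i, j in matches:
            t, d = active[i], detections[j]
            t.kalman = kalman_update(t.kalman, np.array(d.centroid), H_POS, p.R)
            t.centroids.append((frame_index, *d.centroid))
            n = t.hits
            t.mean_area = (t.mean_area * n + d.area) / (n + 1)
            t.hits += 1
            t.misses = 0
            t.last_seen_frame = frame_index
        for i in um_t:
            t = active[i]
            t.misses += 1
            if t.misses > p.max_age:
                t.status = "deleted"
        for j in um_d:
            self.tracks.append(self._new_track(detections[j], frame_index))
        return self.tracks

    def results(self) -> list[Track]:
        """Tracks (any lifecycle state) with at least ``min_hits`` observations."""
        return [t for t in self.tracks if t.hits >= self.params.min_hits]


def track_video(frames, *, tracker_params: TrackerParams | None = None,
                mixture_params: MixtureParams | None = None,
                min_blob_area: float | None = None,
                seed_first_frame: bool = True,
                count_min_area: float | None = None,
                warmup_close_radius: int = 8,
                steady_close_radius: int = 2,
                warmup_frames: int = 15) -> list[Track]:
    """Run the full detect-and-track orbit over a frame sequence.

    Frame 0 initialises the background model; because a background model
    cannot flag objects it was initialised on, frame-0 tracks are seeded
    from the static (Otsu) detector when ``seed_first_frame`` is set.
    Subsequent frames use mixture-model foreground detections.

    Area thresholds default to the reference values rescaled to the
    sequence's calibration.  While the background model is young (the first
    ``warmup_frames``) a cell's motion mask splits into leading/trailing
    crescents around its initialisation ghost, so a generous mask closing
    (``warmup_close_radius``) re-joins them; afterwards masks are solid and
    a small closing (``steady_close_radius``) suffices — keeping the merge
    range short so crossing cells stay separable.
    """
    cal = getattr(frames, "calibration", None)
    if min_blob_area is None:
        min_blob_area = scaled_min_blob_area(cal.um_per_px) if cal else 40.0
    if count_min_area is None:
        count_min_area = scaled_min_area(cal.um_per_px) if cal else 70.0

    tracker = Tracker(tracker_params)
    if len(frames) == 0:
        return []
    model = BackgroundModel(frames[0], mixture_params)
    if seed_first_frame:
        try:
            seed = count_sperm(frames[0], min_area=count_min_area, frame_index=0)
            # Otsu assumes a bimodal histogram; on a nearly empty noisy frame
            # the threshold can collapse into the background noise and flag
            # half the image.  Such a seed is useless — skip it and let
            # tracks start from the first motion detections instead.
            if seed.mask is None or seed.mask.mean() <= 0.1:
                tracker.step(seed.detections, 0)
        except ValueError:
            pass  # constant first frame: nothing to seed
    for i in range(1, len(frames)):
        mask = model.apply(frames[i])
        radius = warmup_close_radius if i < warmup_frames else steady_close_radius
        detections = extract_detections(mask, i, min_blob_area, close_radius=radius)
        tracker.step(detections, i)
    return tracker.results()


# ---------------------------------------------------------------------------
# Tracking-rate scoring
# ---------------------------------------------------------------------------

def tracking_rate(ft: int, fw: int) -> float:
    """Rt = 100·Ft/Fw (%), rounded to 2 decimals (half-up)."""
    if fw <= 0:
        raise ValueError("Fw must be positive")
    if not 0 <= ft <= fw:
        raise ValueError("need 0 <= Ft <= Fw")
    return round_half_up(100.0 * ft / fw, 2)


@dataclass(frozen=True)
class TrackScore:
    """Frames tracked (Ft) out of frames present (Fw), with Rt = 100·Ft/Fw."""

    ft: int
    fw: int
    track_id: int | None = None

    @property
    def rt(self) -> float:
        return tracking_rate(self.ft, self.fw)


def summarize_tracking(scores) -> dict[str, float]:
    """Cohort summary of tracking rates.

    Accepts TrackScore objects or plain Rt percentages; returns the mean
    rate, the percentage of objects tracked in every presence frame
    (Rt = 100) and the percentage tracked less than half the time
    (Rt < 50), each rounded to 2 decimals.
    """
    rts = [s.rt if isinstance(s, TrackScore) else float(s) for s in scores]
    if not rts:
        raise ValueError("empty score list")
    n = len(rts)
    return {
        "mean_rate": round_half_up(float(np.mean(rts)), 2),
        "frac_100": round_half_up(100.0 * sum(r == 100.0 for r in rts) / n, 2),
        "frac_below_50": round_half_up(100.0 * sum(r < 50.0 for r in rts) / n, 2),
    }


def match_tracks_to_truth(tracks: list[Track], truth_centroids: list[np.ndarray],
                          match_dist: float = 16.0) -> list[TrackScore]:
    """Score tracks against ground-truth trajectories.

    Parameters
    ----------
    truth_centroids : list of (n_frames, 2) arrays
        Per-object true (row, col) positions in pixels, NaN rows where the
        object is absent.  Fw is the object's number of non-NaN frames.
    match_dist : float
        A track covers a truth frame when its recorded centroid lies within
        this many pixels of the true position.

    For each truth object, Ft is the best single-identity coverage over all
    tracks — identity switches therefore cost coverage, as they should.
    """
    scores = []
    for tc in truth_centroids:
        tc = np.asarray(tc, dtype=float)
        present = ~np.isnan(tc).any(axis=1)
        fw = int(present.sum())
        if fw == 0:
            continue
        best_ft, best_id = 0, None
        for tr in tracks:
            cov = 0
            for f, r, c in tr.centroids:
                if 0 <= f < len(tc) and present[f]:
                    if np.hypot(r - tc[f, 0], c - tc[f, 1]) <= match_dist:
                        cov += 1
            if cov > best_ft:
                best_ft, best_id = cov, tr.id
        scores.append(TrackScore(ft=best_ft, fw=fw, track_id=best_id))
    return scores
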