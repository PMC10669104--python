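"""Per-track motility kinematics and WHO-style grading.

From a tracked trajectory (positions in µm over time) the standard CASA
descriptors are computed:

* VCL (curvilinear velocity) — total point-to-point path length / duration,
* VSL (straight-line velocity) — net start-to-end displacement / duration,
* VAP (average-path velocity) — length of a smoothed path / duration,
* LIN = 100·VSL/VCL, STR = 100·VSL/VAP, WOB = 100·VAP/VCL (percent).

Cells are then graded A (fast progressive) / B (slow progressive) /
C (non-progressive) / D (immotile) by VCL cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._utils import round_half_up
from .io import Calibration
from .tracking import Track

#: Default VCL cut-offs (µm/s): A ≥ 50 > B ≥ 25 > C ≥ 6 > D.
DEFAULT_GRADE_THRESHOLDS = {"A": 50.0, "B": 25.0, "C": 6.0}

#: Tracks shorter than this many points give unstable velocity estimates.
MIN_TRACK_POINTS = 15


@dataclass(frozen=True)
class Trajectory:
    """Ordered positions (µm) with timestamps (s)."""

    positions: np.ndarray  # (n, 2) µm
    times: np.ndarray      # (n,) s

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float).reshape(-1, 2))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float).reshape(-1))
        if len(self.positions) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if len(self.positions) != len(self.times):
            raise ValueError("positions and times differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @classmethod
    def from_track(cls, track: Track, calibration: Calibration) -> "Trajectory":
        """Convert a pixel-space track to physical units."""
        arr = np.asarray(track.centroids, dtype=float)
        frames, pos = arr[:, 0], arr[:, 1:3]
        return cls(pos * calibration.um_per_px, frames / calibration.fps)


@dataclass
class MotilityRecord:
    """Kinematic descriptors for one track; velocities µm/s, ratios %."""

    track_id: int
    vcl: float
    vsl: float
    vap: float
    lin: float
    str_: float
    wob: float
    grade: str | None = None
    n_points: int = 0
    sufficient: bool = True

    def rounded(self, ndigits: int = 2) -> "MotilityRecord":
        """Copy with all numeric fields rounded half-up for reporting."""
        return replace(self, vcl=round_half_up(self.vcl, ndigits),
                       vsl=round_half_up(self.vsl, ndigits),
                       vap=round_half_up(self.vap, ndigits),
                       lin=round_half_up(self.lin, ndigits),
                       str_=round_half_up(self.str_, ndigits),
                       wob=round_half_up(self.wob, ndigits))


def curvilinear_length(traj: Trajectory) -> float:
    """L: sum of consecutive Euclidean segment lengths (µm)."""
    return float(np.linalg.norm(np.diff(traj.positions, axis=0), axis=1).sum())


def average_path(traj: Trajectory, window: int = 5) -> Trajectory:
    """Centered moving average of the positions ("average path").

    ``window`` must be odd; near the ends the window shrinks symmetrically,
    so the first and last points are preserved and window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(traj.positions)
    half = window // 2
    smoothed = np.empty_like(traj.positions)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        smoothed[i] = traj.positions[i - k:i + k + 1].mean(axis=0)
    return Trajectory(smoothed, traj.times)


def _ratio_pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 1e-12 else float("nan")


def compute_kinematics(traj: Trajectory, window: int = 5, track_id: int = 0,
                       min_points: int = MIN_TRACK_POINTS) -> MotilityRecord:
    """VCL/VSL/VAP and the LIN/STR/WOB ratios for one trajectory.

    Ratios are stored at full precision (use :meth:`MotilityRecord.rounded`
    for 2-decimal reporting); an immotile cell (VCL ≈ 0) has undefined
    ratios, reported as NaN.  Tracks with fewer than ``min_points`` points
    are computed anyway but flagged ``sufficient=False``.
    """
    T = traj.duration
    if T <= 0:
        raise ValueError("trajectory duration must be positive")
    L = curvilinear_length(traj)
    vsl_disp = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    S = curvilinear_length(average_path(traj, window)) if window > 1 else L
    vcl, vsl, vap = L / T, vsl_disp / T, S / T
    return MotilityRecord(
        track_id=track_id, vcl=vcl, vsl=vsl, vap=vap,
        lin=_ratio_pct(vsl, vcl), str_=_ratio_pct(vsl, vap), wob=_ratio_pct(vap, vcl),
        n_points=len(traj.positions), sufficient=len(traj.positions) >= min_points,
    )


def grade(record: MotilityRecord | float, thresholds: dict[str, float] | None = None) -> str:
    """Grade a cell A/B/C/D from its VCL (µm/s)."""
    th = thresholds or DEFAULT_GRADE_THRESHOLDS
    vcl = record.vcl if isinstance(record, MotilityRecord) else float(record)
    if vcl >= th["A"]:
        return "A"
    if vcl >= th["B"]:
        return "B"
    if vcl >= th["C"]:
        return "C"
    return "D"


def grade_records(records: list[MotilityRecord],
                  thresholds: dict[str, float] | None = None) -> list[MotilityRecord]:
    for r in records:
        r.grade = grade(r, thresholds)
    return records


def summarize_cohort(records: list[MotilityRecord]) -> dict:
    """Grade counts/percentages and parameter statistics for a cohort.

    Records without a grade are graded with the default thresholds first.
    NaN ratios (immotile cells) are excluded from the ratio statistics.
    """
    if not records:
        raise ValueError("empty cohort")
    counts = {g: 0 for g in "ABCD"}
    for r in records:
        counts[r.grade or grade(r)] += 1
    n = len(records)
    pct = {g: round_half_up(100.0 * c / n, 2) for g, c in counts.items()}
    params = {}
    for name in ("vcl", "vsl", "vap", "lin", "str_", "wob"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        vals = vals[np.isfinite(vals)]
        params[name.rstrip("_")] = {
            "mean": round_half_up(float(vals.mean()), 2) if vals.size else float("nan"),
            "median": round_half_up(float(np.median(vals)), 2) if vals.size else float("nan"),
        }
    return {"n": n, "grade_counts": counts, "grade_percent": pct, "parameters": params}


def analyze_tracks(tracks: list[Track], calibration: Calibration, window: int = 5,
                   thresholds: dict[str, float] | None = None,
                   min_points: int = MIN_TRACK_POINTS) -> list[MotilityRecord]:
    """Kinematics + grade for every track with at least 2 points."""
    records = []
    for t in tracks:
        if len(t.centroids) < 2:
            continue
        traj = Trajectory.from_track(t, calibration)
        if traj.duration <= 0:
            continue
        rec = compute_kinematics(traj, window=window, track_id=t.id, min_points=min_points)
        rec.grade = grade(rec, thresholds)
        records.append(rec)
    return records
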