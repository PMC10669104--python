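"""End-to-end pipeline orchestration and machine-readable reports.

One :class:`RunConfig` fully determines a run: given the same input video it
reproduces byte-identical CSV/JSON outputs.  The report bundle mirrors what
a clinic-style app would show — per-frame counts, per-track trajectories and
tracking scores, per-track kinematics with grades, and a cohort summary with
the grade distribution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .background import MixtureParams, scaled_min_blob_area
from .count import count_sperm, scaled_min_area
from .io import Calibration, FrameSequence, load_frames
from .motility import MIN_TRACK_POINTS, analyze_tracks, summarize_cohort
from .tracking import Track, TrackerParams, track_video, tracking_rate

log = logging.getLogger("spermtrack")


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    input: str | None = None
    um_per_px: float = 0.074
    fps: float = 29.80
    # static count
    level: float | None = None          # None → Otsu
    open_radius: int = 1
    min_area: float | None = None       # None → scaled from calibration
    # motion detection
    mixture: MixtureParams = field(default_factory=MixtureParams)
    min_blob_area: float | None = None  # None → scaled from calibration
    # tracking
    tracker: TrackerParams = field(default_factory=TrackerParams)
    seed_first_frame: bool = True
    # motility
    window: int = 5
    min_track_points: int = MIN_TRACK_POINTS
    out_dir: str = "spermtrack_out"
    seed: int = 0

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.um_per_px, self.fps)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("mixture"), dict):
            d["mixture"] = MixtureParams(**d["mixture"])
        if isinstance(d.get("tracker"), dict):
            d["tracker"] = TrackerParams(**d["tracker"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [(t.id, f, r, c) for t in tracks for f, r, c in t.centroids]
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col"])


def track_scores_frame(tracks: list[Track]) -> pd.DataFrame:
    """Per-track lifecycle table: id, appear, disappear, Ft, Fw, Rt.

    Without ground truth, Fw is taken as the track's observation window
    (last seen − appear + 1); Ft is the number of frames actually matched,
    so Rt < 100 exactly when the tracker coasted through missed frames.
    """
    rows = []
    for t in tracks:
        fw = t.last_seen_frame - t.appear_frame + 1
        rows.append((t.id, t.appear_frame, t.last_seen_frame, t.frames_tracked, fw,
                     tracking_rate(t.frames_tracked, fw)))
    return pd.DataFrame(rows, columns=["id", "appear", "disappear", "ft", "fw", "rt"])


def run_full_pipeline(config: RunConfig, frames: FrameSequence | None = None) -> dict:
    """Run count → detect/track → kinematics → grade and write the report.

    Returns the report bundle (also written to ``config.out_dir`` as
    counts.csv, tracks.csv, track_scores.csv, motility.csv, summary.json,
    config.yaml).  ``frames`` may be passed directly (e.g. a simulated
    scene); otherwise ``config.input`` is loaded.
    """
    if frames is None:
        if config.input is None:
            raise ValueError("either frames or config.input is required")
        frames = load_frames(config.input, config.calibration)
    cal = frames.calibration
    min_area = config.min_area if config.min_area is not None else scaled_min_area(cal.um_per_px)
    min_blob = config.min_blob_area if config.min_blob_area is not None \
        else scaled_min_blob_area(cal.um_per_px)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("counting %d frames", len(frames))
    counts = []
    for i in range(len(frames)):
        try:
            res = count_sperm(frames[i], level=config.level, open_radius=config.open_radius,
                              min_area=min_area, frame_index=i)
            counts.append((i, res.count))
        except ValueError:  # constant frame: nothing segmentable
            counts.append((i, 0))
    counts_df = pd.DataFrame(counts, columns=["frame", "count"])

    log.info("tracking")
    tracks = track_video(frames, tracker_params=config.tracker, mixture_params=config.mixture,
                         min_blob_area=min_blob, seed_first_frame=config.seed_first_frame,
                         count_min_area=min_area)
    tracks_df = tracks_to_frame(tracks)
    scores_df = track_scores_frame(tracks)

    log.info("kinematics for %d tracks", len(tracks))
    records = analyze_tracks(tracks, cal, window=config.window,
                             min_points=config.min_track_points)
    usable = [r for r in records if r.sufficient]
    mot_rows = [
        (r.track_id, *(getattr(r.rounded(), f) for f in ("vcl", "vsl", "vap", "lin", "str_", "wob")),
         r.grade, r.n_points, r.sufficient)
        for r in records
    ]
    motility_df = pd.DataFrame(
        mot_rows, columns=["id", "vcl", "vsl", "vap", "lin", "str", "wob",
                           "grade", "n_points", "sufficient"])

    if usable:
        cohort = summarize_cohort(usable)
        status = "ok"
    else:
        cohort = {"n": 0, "grade_counts": {g: 0 for g in "ABCD"},
                  "grade_percent": {g: 0.0 for g in "ABCD"}, "parameters": {}}
        status = "no sperm detected"

    summary = {
        "status": status,
        "n_frames": len(frames),
        "mean_count": float(counts_df["count"].mean()) if len(counts_df) else 0.0,
        "n_tracks": len(tracks),
        "n_graded": len(usable),
        "cohort": cohort,
        "config": config.to_dict(),
    }

    counts_df.to_csv(out / "counts.csv", index=False)
    tracks_df.to_csv(out / "tracks.csv", index=False, float_format="%.3f")
    scores_df.to_csv(out / "track_scores.csv", index=False)
    motility_df.to_csv(out / "motility.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")

    return {"counts": counts_df, "tracks": tracks_df, "track_scores": scores_df,
            "motility": motility_df, "summary": summary, "track_objects": tracks}


def plot_trajectories(tracks: list[Track], path: str | Path | None = None, ax=None):
    """Draw every track's centroid polyline (pixel coordinates, origin top-left)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for t in tracks:
        arr = np.asarray(t.centroids, dtype=float)
        if len(arr) < 2:
            continue
        ax.plot(arr[:, 2], arr[:, 1], lw=1)
        ax.plot(arr[0, 2], arr[0, 1], "s", ms=3, color="green")
    ax.invert_yaxis()
    ax.set_xlabel("col (px)")
    ax.set_ylabel("row (px)")
    ax.set_title("sperm trajectories")
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax
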