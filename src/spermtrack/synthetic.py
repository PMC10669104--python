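"""Seeded synthetic microscopy videos with exact ground truth.

The generator emulates the phenomenology of flash-illuminated brightfield
sperm video: bright head-sized ellipses (≈8×4 µm) over a noisy darker
background.  Progressive cells swim along straight or gently curved mean
paths with a sinusoidal lateral oscillation (the forward zigzag),
non-progressive cells jitter about a fixed point, immotile cells are
static, and debris is rendered below the impurity-area threshold.  All
randomness comes from one seeded generator, so a config reproduces its
video and truth bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Calibration, FrameSequence
from .motility import MotilityRecord, Trajectory, compute_kinematics, grade

SPERM_CLASSES = ("progressive", "nonprogressive", "immotile")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    The default desk-scale scene is 512×512 px at 0.5 µm/px and 30 fps for
    90 frames (3 s), matching the order of magnitude of a hand-held
    recording while keeping test runtimes in seconds.
    """

    shape: tuple[int, int] = (512, 512)
    calibration: Calibration = field(default_factory=lambda: Calibration(um_per_px=0.5, fps=30.0))
    n_frames: int = 90
    n_progressive: int = 6
    n_nonprogressive: int = 3
    n_immotile: int = 3
    n_debris: int = 5
    progressive_speed: tuple[float, float] = (20.0, 50.0)  # µm/s
    nonprogressive_jitter_um: float = 1.0                  # per-frame jitter σ
    zigzag_amplitude_um: float = 2.0
    zigzag_period: int = 10                                # frames
    turn_rate_deg: float = 0.5                             # max mean-path curvature/frame
    head_length_um: float = 8.0
    head_width_um: float = 4.0
    background: float = 60.0
    object_intensity: float = 200.0
    debris_intensity: float = 180.0
    noise_sigma: float = 3.0
    layout: str = "random"                                 # "random" | "lanes"
    margin_px: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_frames", "n_progressive", "n_nonprogressive", "n_immotile", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.progressive_speed) < 0:
            raise ValueError("speeds must be non-negative")
        head_px = self.head_length_um / self.calibration.um_per_px
        if head_px >= min(self.shape) - 2 * self.margin_px:
            raise ValueError("objects larger than the usable frame area")


@dataclass
class TruthObject:
    """Ground truth for one rendered object."""

    id: int
    cls: str
    centroids_px: np.ndarray   # (n_frames, 2) float (row, col); NaN when absent
    orientations: np.ndarray   # (n_frames,) radians
    speed_um_s: float = 0.0

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.centroids_px).any(axis=1)

    @property
    def fw(self) -> int:
        return int(self.present.sum())


@dataclass
class GroundTruth:
    """Exact per-object and per-frame truth for a simulated scene."""

    objects: list[TruthObject]
    calibration: Calibration
    n_frames: int

    def sperm_objects(self, motile_only: bool = False) -> list[TruthObject]:
        classes = ("progressive", "nonprogressive") if motile_only else SPERM_CLASSES
        return [o for o in self.objects if o.cls in classes]

    @property
    def count_per_frame(self) -> np.ndarray:
        """Number of sperm-sized objects (debris excluded) in each frame."""
        counts = np.zeros(self.n_frames, dtype=int)
        for o in self.sperm_objects():
            counts += o.present
        return counts

    def centroids_px(self, motile_only: bool = True) -> list[np.ndarray]:
        """Per-object (row, col) pixel trajectories, for tracker scoring."""
        return [o.centroids_px for o in self.sperm_objects(motile_only)]


def _mean_path(rng, cfg: SceneConfig, start, heading, step_px, turn_rad):
    """Mean path with constant curvature, bouncing off the margins."""
    h, w = cfg.shape
    lo, hi_r, hi_c = cfg.margin_px, h - cfg.margin_px, w - cfg.margin_px
    pos = np.array(start, dtype=float)
    theta = heading
    path, headings = [pos.copy()], [theta]
    for _ in range(cfg.n_frames - 1):
        step = step_px * np.array([math.sin(theta), math.cos(theta)])
        nxt = pos + step
        if not lo <= nxt[0] <= hi_r:
            theta = -theta
            nxt = pos + step_px * np.array([math.sin(theta), math.cos(theta)])
        if not lo <= nxt[1] <= hi_c:
            theta = math.pi - theta
            nxt = pos + step_px * np.array([math.sin(theta), math.cos(theta)])
        pos = np.clip(nxt, [lo, lo], [hi_r, hi_c])
        theta += turn_rad
        path.append(pos.copy())
        headings.append(theta)
    return np.array(path), np.array(headings)


def _build_objects(rng: np.random.Generator, cfg: SceneConfig) -> list[TruthObject]:
    cal = cfg.calibration
    px = cal.um_per_px
    objects: list[TruthObject] = []
    oid = 0
    h, w = cfg.shape
    amp_px = cfg.zigzag_amplitude_um / px

    for i in range(cfg.n_progressive):
        speed = rng.uniform(*cfg.progressive_speed) if cfg.progressive_speed[0] < cfg.progressive_speed[1] \
            else cfg.progressive_speed[0]
        step_px = speed / cal.fps / px
        if cfg.layout == "lanes":
            row = (i + 1) * h / (cfg.n_progressive + 1)
            going_right = i % 2 == 0
            col = cfg.margin_px + 20 if going_right else w - cfg.margin_px - 20
            heading = 0.0 if going_right else math.pi  # ±col direction
            turn = 0.0
        else:
            row = rng.uniform(cfg.margin_px, h - cfg.margin_px)
            col = rng.uniform(cfg.margin_px, w - cfg.margin_px)
            heading = rng.uniform(0, 2 * math.pi)
            turn = math.radians(rng.uniform(-cfg.turn_rate_deg, cfg.turn_rate_deg))
        mean, headings = _mean_path(rng, cfg, (row, col), heading, step_px, turn)
        phase = rng.uniform(0, 2 * math.pi)
        t = np.arange(cfg.n_frames)
        lateral = amp_px * np.sin(2 * math.pi * t / cfg.zigzag_period + phase) if amp_px > 0 \
            else np.zeros(cfg.n_frames)
        normal = np.stack([np.cos(headings), -np.sin(headings)], axis=1)
        centroids = mean + lateral[:, None] * normal
        objects.append(TruthObject(oid, "progressive", centroids, headings, speed))
        oid += 1

    jitter_px = cfg.nonprogressive_jitter_um / px
    for _ in range(cfg.n_nonprogressive):
        anchor = np.array([rng.uniform(cfg.margin_px, h - cfg.margin_px),
                           rng.uniform(cfg.margin_px, w - cfg.margin_px)])
        centroids = anchor[None, :] + rng.normal(0, jitter_px, size=(cfg.n_frames, 2))
        theta = rng.uniform(0, 2 * math.pi)
        objects.append(TruthObject(oid, "nonprogressive", centroids,
                                   np.full(cfg.n_frames, theta)))
        oid += 1

    for _ in range(cfg.n_immotile):
        anchor = np.array([rng.uniform(cfg.margin_px, h - cfg.margin_px),
                           rng.uniform(cfg.margin_px, w - cfg.margin_px)])
        theta = rng.uniform(0, 2 * math.pi)
        objects.append(TruthObject(oid, "immotile",
                                   np.repeat(anchor[None, :], cfg.n_frames, axis=0),
                                   np.full(cfg.n_frames, theta)))
        oid += 1

    for _ in range(cfg.n_debris):
        anchor = np.array([rng.uniform(cfg.margin_px, h - cfg.margin_px),
                           rng.uniform(cfg.margin_px, w - cfg.margin_px)])
        objects.append(TruthObject(oid, "debris",
                                   np.repeat(anchor[None, :], cfg.n_frames, axis=0),
                                   np.zeros(cfg.n_frames)))
        oid += 1
    return objects


def _render_ellipse(img: np.ndarray, center, theta: float, a: float, b: float,
                    background: float, intensity: float, edge: float = 0.25):
    """Paint a soft-edged oriented ellipse; overlapping objects take the max."""
    h, w = img.shape
    r0, c0 = center
    pad = a + 2.0
    rmin, rmax = max(0, int(r0 - pad)), min(h, int(r0 + pad) + 1)
    cmin, cmax = max(0, int(c0 - pad)), min(w, int(c0 + pad) + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.meshgrid(np.arange(rmin, rmax) - r0, np.arange(cmin, cmax) - c0, indexing="ij")
    # rotate into the ellipse frame: long axis along the heading
    u = rr * math.sin(theta) + cc * math.cos(theta)
    v = rr * math.cos(theta) - cc * math.sin(theta)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    f = np.clip((1.0 + edge - r) / (2.0 * edge), 0.0, 1.0)
    patch = background + (intensity - background) * f
    np.maximum(img[rmin:rmax, cmin:cmax], patch, out=img[rmin:rmax, cmin:cmax])


def simulate_video(config: SceneConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render the scene and return (frames, exact ground truth).

    The same config (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    objects = _build_objects(rng, config)
    cal = config.calibration
    a = config.head_length_um / 2.0 / cal.um_per_px
    b = config.head_width_um / 2.0 / cal.um_per_px
    h, w = config.shape
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    for t in range(config.n_frames):
        img = np.full((h, w), config.background, dtype=float)
        for o in objects:
            if not o.present[t]:
                continue
            if o.cls == "debris":
                r, c = np.rint(o.centroids_px[t]).astype(int)
                if 0 <= r < h and 0 <= c < w:
                    img[r, c] = max(img[r, c], config.debris_intensity)
            else:
                _render_ellipse(img, o.centroids_px[t], o.orientations[t], a, b,
                                config.background, config.object_intensity)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    seq = FrameSequence(frames, cal)
    return seq, GroundTruth(objects, cal, config.n_frames)


def truth_kinematics(truth: GroundTruth, calibration: Calibration | None = None,
                     window: int = 5) -> list[MotilityRecord]:
    """Apply the motility computations to the *true* centroids.

    This is the oracle side of parameter-recovery tests: the same
    kinematics code, fed exact positions instead of tracked ones.
    """
    cal = calibration or truth.calibration
    records = []
    for o in truth.sperm_objects():
        pos_um = o.centroids_px * cal.um_per_px
        times = np.flatnonzero(o.present) / cal.fps
        pos_um = pos_um[o.present]
        if len(pos_um) < 2:
            continue
        if np.allclose(pos_um, pos_um[0]):
            rec = MotilityRecord(track_id=o.id, vcl=0.0, vsl=0.0, vap=0.0,
                                 lin=float("nan"), str_=float("nan"), wob=float("nan"),
                                 n_points=len(pos_um))
        else:
            rec = compute_kinematics(Trajectory(pos_um, times), window=window, track_id=o.id)
        rec.grade = grade(rec)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Scene presets — the standard study conditions used throughout the tests
# ---------------------------------------------------------------------------

def default_scene(seed: int = 0) -> SceneConfig:
    """Mixed default scene: 6 progressive, 3 non-progressive, 3 immotile, 5 debris."""
    return SceneConfig(seed=seed)

def well_separated_scene(seed: int = 0) -> SceneConfig:
    """Progressive swimmers on parallel lanes that never approach each other."""
    return SceneConfig(n_progressive=5, n_nonprogressive=0, n_immotile=0, n_debris=3,
                       progressive_speed=(15.0, 35.0), layout="lanes", turn_rate_deg=0.0,
                       seed=seed)

def crowded_scene(seed: int = 0) -> SceneConfig:
    """Denser scene with crossings, immotile cells and debris."""
    return SceneConfig(n_progressive=12, n_nonprogressive=0, n_immotile=4, n_debris=8,
                       seed=seed)

def single_swimmer_scene(speed_um_s: float = 25.0, *, zigzag: bool = False,
                         noise_sigma: float = 3.0, seed: int = 0) -> SceneConfig:
    """One progressive swimmer at a fixed speed, for kinematics recovery."""
    return SceneConfig(n_progressive=1, n_nonprogressive=0, n_immotile=0, n_debris=0,
                       progressive_speed=(speed_um_s, speed_um_s), layout="lanes",
                       turn_rate_deg=0.0,
                       zigzag_amplitude_um=2.0 if zigzag else 0.0,
                       noise_sigma=noise_sigma, seed=seed)
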