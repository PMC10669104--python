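# Methods

This note describes the models and procedures implemented in `spermtrack`,
the defaults and why they were chosen, what the synthetic scenes do and do
not emulate, and the numerical conventions that make results reproducible.

## Conventions and calibration

Images are 8-bit grayscale; colour input is converted with the BT.601 luma
weights 0.299/0.587/0.114. Coordinates are (row, col), 0-based, origin
top-left; centroids are real-valued. All detection and tracking happens in
pixels and frames; physical units enter exactly once, when a track is turned
into a trajectory via the calibration (µm/px and fps). The default
calibration, 0.074 µm/px at 29.80 fps, matches the hand-held acquisition
geometry the area defaults were tuned at; the synthetic desk scenes use
0.5 µm/px at 30 fps.

Percentages in reports are rounded half-up to 2 decimals, implemented with
decimal arithmetic so that ties never fall to banker's rounding.

## Static counting

The count of all cells (moving and stationary) is taken per frame:

1. Otsu threshold over the 256-bin histogram, maximising the between-class
   variance σ²_B(t) = ω₀ω₁(µ₀ − µ₁)². When several thresholds tie, the
   midpoint of the tying plateau is returned — symmetric and deterministic.
   A constant image raises (`degenerate histogram`). Binarisation keeps
   pixels strictly above `level·255` (bright cells on a dark background;
   a polarity flag inverts first for dark-on-bright input).
2. Hole filling, then binary opening with a disk (default radius 1) to
   detach touching cells and shave noise.
3. Small-object removal: 8-connected components below `min_area` are
   impurities (white blood cells, dust). The reference value is 70 px at
   0.074 µm/px; for other calibrations it is rescaled by
   (0.074/µm_per_px)² and floored at 4 px, because a sub-4-pixel area
   threshold cannot reject single-pixel sensor noise regardless of what the
   scaling rule says.
4. 8-connected labelling, with **area-based declumping**: opening cannot
   separate cells whose bodies genuinely overlap, so a component larger
   than 1.6× the median component area (the median is a robust single-cell
   size estimate when most cells are isolated) is split into
   `round(area/median)` cells by k-means on its pixel coordinates
   (deterministic seed). Components more than 6× the median are treated as
   segmentation failures and kept whole — this also guards against a
   collapsed threshold producing one giant blob.

Known failure mode: Otsu assumes a roughly bimodal histogram. On a nearly
empty noisy frame the foreground class is too small and the threshold falls
inside the background noise. Callers that may see such frames should pass a
fixed level; the tracker's frame-0 seeding discards an Otsu mask covering
more than 10 % of the frame for this reason.

## Background mixture and motion detection

Each pixel's intensity is modelled as a mixture of K = 3 Gaussians
(weight ω, mean µ, variance σ²). Per frame, the current value matches the
first component (in ω/σ-descending order) with |X − µ| ≤ λσ, λ = 2.5.
Matched components move toward the sample with learning rate α; unmatched
weights decay by (1 − α); if nothing matches, the lowest-ranked component is
replaced by (µ = X, σ² = σ₀², ω = 0.05). Weights are renormalised every
step and variances floored at (4 gray levels)². Background is the smallest
prefix of the ω/σ ranking whose cumulative weight exceeds ξ = 0.7; a pixel
is foreground when it matches no background component. Classification uses
the pre-update state, so a change is flagged in the frame it occurs.

Defaults (α = 0.01, λ = 2.5, ξ = 0.7, σ₀ = 15, floor 4) are the standard
adaptive-mixture operating point; all are config-exposed since microscopy
contrast varies. While the model is young the effective learning rate
follows the 1/t schedule, `max(α, 1/t)` — the usual initialisation
convention — so cells that were present in the first frame (and therefore
learned into the model) are absorbed within a few frames instead of
lingering as "ghost" foreground for ~1/α frames.

Foreground masks are turned into detections by (a) dropping sub-4-px
speckle, (b) a binary closing that re-joins fragmented blobs, and
(c) keeping 8-connected components ≥ `min_blob_area` (40 px reference,
rescaled and floored like `min_area`) as centroid detections.

## Tracking

State per cell: x = (row, col, v_row, v_col) with dt = 1 frame,
constant-velocity transition A, position observation H. Predict:
x̂⁻ = A x̂, P⁻ = A P Aᵀ + Q. Update: K = P⁻Hᵀ(HP⁻Hᵀ + R)⁻¹,
x̂ = x̂⁻ + K(z − Hx̂⁻), P = (I − KH)P⁻, with P symmetrised after each
update. Defaults Q = 0.01·I, R = I, P₀ = diag(1, 1, 10, 10); new tracks
start with zero velocity (no prior motion information).

Association is the minimum-total-Euclidean-cost one-to-one assignment
between predicted positions and detections; an optimal pair farther apart
than the gate (50 px) is demoted to unmatched. The gate bounds per-frame
displacement plus prediction error, which is a property of motion and frame
rate rather than of pixel size, so it is deliberately **not** rescaled with
calibration (rescaling 50 px from the reference calibration down to a desk
scene would give 7.4 px, smaller than one inter-frame step of a fast cell).

Lifecycle: matched tracks are Kalman-updated and record the *measured*
centroid (recording measurements rather than filtered states keeps VCL
unbiased); unmatched tracks coast on prediction and die after
`max_age = 5` consecutive misses; unmatched detections spawn fresh,
monotonically increasing IDs that are never reused.

`track_video` composes the stages. Because a background model initialised
on frame 0 cannot flag the objects it was initialised on, frame-0 tracks
are seeded from the static detector (mirroring the detect-first-frame step
of the tracking procedure). During the model's warm-up (first 15 frames) a
moving cell's mask splits into leading/trailing crescents around its
initialisation ghost, so the mask closing uses a generous radius 8 there
and a small radius 2 afterwards — keeping the steady-state merge range
short so crossing cells remain separable. On crowded simulated scenes this
two-phase closing raised the mean tracking rate from ~75–80 % to 82–99 %
across seeds without touching the lifecycle defaults.

Scoring: Rt = 100·Ft/Fw. Against ground truth, Fw is the object's presence
frames and Ft the best single-identity coverage within a 16 px match radius
(identity switches cost coverage, as they should). Without ground truth,
reports take Fw as the track's observation window.

## Kinematics and grading

Trajectories (µm, s) require ≥ 2 points and strictly increasing times.
VCL = L/T with L the polyline segment sum; VSL from net displacement;
VAP = S/T with S the segment sum of a centred moving average (default
window 5 frames, the common CASA convention; window 1 disables smoothing
and makes VAP ≡ VCL). The window shrinks symmetrically at the ends, so
endpoints are preserved and a straight line is a fixed point of the
smoothing. Ratios are stored at full precision; LIN = STR·WOB/100 holds
identically before rounding. An immotile cell (VCL ≈ 0) has undefined
ratios, reported as NaN and excluded from cohort ratio statistics.

Tracks shorter than 15 points (~0.5 s at 29.80 fps) give unstable velocity
estimates; they are computed but flagged insufficient and excluded from
cohort summaries. Grades use VCL cut-offs A ≥ 50 > B ≥ 25 > C ≥ 6 > D
(µm/s), the rule that exactly reproduces the bundled benchmark table's
grade column; all cut-offs are configurable because WHO-style grading is
usually phrased in progressive-motility terms that a VCL-only rule can only
approximate.

## Sharpness

SDF sums |I(x,y) − I(x,y−1)| and |I(x,y) − I(x+1,y)| over in-bounds pairs
and divides by the pixel count M·N. TDF applies the 3×3 Sobel kernels,
forms S = √(Gx² + Gy²), and averages S² over the interior (border pixels,
where the kernel overhangs, are excluded rather than padded — padding
choices change values, exclusion is reproducible). A literal-sum variant
S = Gx + Gy is available behind a flag. Both measures are zero iff the
(interior of the) image is constant, are invariant to constant offsets, and
decrease under blur. Sequence scores are normalised by the series maximum;
an all-constant sequence normalises to zeros.

## Synthetic scenes

The generator emulates flash-illuminated brightfield video: bright
soft-edged ellipses (head 8×4 µm) over background 60 with Gaussian sensor
noise σ = 3 gray levels, object peak 200. Progressive cells follow straight
or gently curved mean paths (≤ 0.5°/frame) at 20–50 µm/s with a sinusoidal
lateral oscillation (amplitude 2 µm, period 10 frames) — the forward zigzag
— bouncing off frame margins; non-progressive cells jitter about a fixed
anchor (σ = 1 µm/frame); immotile cells are static; debris is rendered as
single bright pixels, below any resolvable area threshold. The default desk
scene is 512×512 px at 0.5 µm/px, 30 fps, 90 frames (3 s), with
6 progressive + 3 non-progressive + 3 immotile cells and 5 debris — sized
so full-pipeline tests run in seconds; the full 3840×2160 geometry is a
config away. One seeded generator drives all randomness: the same config is
bit-reproducible.

Ground truth stores exact per-frame centroids per object; truth kinematics
apply the package's own trajectory code to those centroids (truth VCL is
defined on the sampled polyline, not the continuous curve, so pipeline
comparisons are like-for-like).

What the simulator does **not** emulate: flagellar beating and its
intensity flicker, hydrodynamic interactions, cell collisions (ellipses may
overlap, which real monolayer cells cannot — this makes the counting test
*harder* than reality), illumination drift, and optical aberrations.
Passing tests therefore demonstrate the correctness of the measurement
chain under controlled conditions, not performance on any particular
instrument's footage.

## Problem sizes and test design

The bundled benchmark tables (17 tracking rows, 10 motility rows) exercise
the rate/ratio arithmetic against independently printed values; one
tracking row's printed rate was truncated rather than rounded by its source
(100·44/68 = 64.7059 printed as 64.70), and tests accept that row to one
unit in the last printed digit. Recovery experiments use 90-frame 512×512
scenes (counting error over 20-frame scenes; tracking on separated-lane and
crowded presets; speed recovery on a single 25 µm/s swimmer). The
acceptance script averages the counting error over three independent scenes
because the error is dominated by rare adhered-cell events and a single
short scene estimates it with high variance.

## Known limitations

* Motion-based detection cannot see immotile cells (static-count only) and
  detects place-trembling non-progressive cells unreliably once the
  background model has absorbed their average appearance; their grades come
  out D/C only when a track happens to persist.
* Otsu thresholding needs a bimodal histogram (see above).
* Prolonged cell-cell contact (longer than `max_age` frames of merged
  blobs) still breaks identities; multi-hypothesis tracking and
  appearance-based re-identification are out of scope.
* Declumping estimates cell count from area only; it places split centroids
  by k-means, which is adequate for counting but approximate for tracking
  through contact.
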