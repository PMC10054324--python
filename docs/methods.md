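# Methods

This note documents the models, parameter choices and numerical decisions
behind `stereofauna`, and what the synthetic-scene tests do and do not show
about real recordings.

## Camera model and rectification

Cameras follow the pinhole model extended with Brown–Conrady distortion:
for a normalized ray (x, y) = (X/Z, Y/Z), with r² = x² + y²,

    x' = x(1 + k1 r² + k2 r⁴ + k3 r⁶) + 2 p1 x y + p2 (r² + 2x²)
    y' = y(1 + k1 r² + k2 r⁴ + k3 r⁶) + p1 (r² + 2y²) + 2 p2 x y

and pixels u = fx·x' + cx, v = fy·y' + cy. All five coefficients are
supported; any may be zero. Refraction at the flat housing port is **not**
ray-traced: an in-situ calibration absorbs it into the intrinsics and
distortion, which leaves a small systematic error (the single-viewpoint
assumption is strictly false behind a flat port) that is accepted as below
the random measurement error at working distances.

Extrinsics use the `X_right = R·X_left + t` convention, translation in mm.
Rectification takes the new x-axis along the baseline, the y-axis as close
as possible to the left camera's y-axis, and gives both virtual cameras the
mean focal length and principal point of the pair. Triangulation uses the
rectified disparity relation z = f·B/d and maps back to the left-camera
frame. Row disagreement beyond a configurable epipolar tolerance (default
2 px) logs a warning and the rows are averaged; the tolerance is a
diagnostic gate, not a rejection.

Numerical choices:

* **Undistortion** inverts the distortion polynomial by fixed-point
  iteration in normalized coordinates, at most 30 rounds, stopping when the
  step falls below 1e-13 normalized units. The tight tolerance matters:
  depth error amplifies pixel error by z²/(f·B), so keeping the
  project→triangulate round trip below 1e-6 mm at z = 5 m requires
  sub-1e-9-pixel inversion accuracy. For coefficients far outside the
  calibrated regime the iteration can diverge; this is detected and raised.
* Points at or behind an optical center are rejected rather than clamped.

## Synthetic scenes

The generator emulates the recording conditions of a stationary two-camera
observatory: 120 mm baseline, 1280×1024 monochrome sensors, up to 20 fps,
and a 9×8-square / 50 mm checkerboard for validation, with targets at
0.5–2.0 m working distance.

* **Targets** are 3D ellipsoids (length × height × width) following
  piecewise-linear waypoint trajectories. A ground-truth box is the
  image-axis-aligned hull of 26 projected surface extremal points — the
  generator's operational definition of "what a box corner means in 3D".
  For strictly fronto-parallel size checks a near-zero width collapses the
  ellipsoid to a plate.
* **Detection noise** is applied after projection: i.i.d. Gaussian corner
  jitter, per-detection dropout, Poisson false positives with random boxes
  and labels, label confusion, and Beta-distributed confidences —
  Beta(8, 2) for true positives, Beta(2, 5) for clutter — chosen to give
  usable precision–recall curves; none of these values is fitted to data.
* **Rendering** draws targets as filled ellipses over a static spatial
  pattern plus per-frame Gaussian sensor noise, sufficient for background-
  subtraction tests.

What the generator does **not** emulate: turbidity and backscatter,
lighting drift, fish articulation and out-of-plane pose, occlusion within
schools, H.264 compression artifacts. Passing synthetic tests therefore
demonstrates the correctness of the geometry, matching, counting and
evaluation logic under controlled noise — not detector performance or
measurement accuracy on real footage.

## Activity detection

Each pixel's intensity history is modelled by an online mixture of up to
K = 5 Gaussians in the adaptive (Zivkovic-style) scheme: the best-matching
component (gate: squared error < 16·variance) receives the update with rate
ρ = α/w, weights relax toward ownership with α = 1/history
(history = 100 frames), unmatched pixels replace the lightest component,
and the heaviest components holding 90% of the weight form the background.
Frames are median-filtered (5 px) first to suppress particle speckle.
Frames whose foreground fraction exceeds 0.001 are active; active runs
separated by at most 10 frames merge, and runs shorter than 5 frames are
dropped.

These defaults are deliberately recall-oriented: the stage's job is to
discard empty water without ever missing an animal, and false alarms only
cost downstream compute. The stage is optional — in an online deployment
the detector itself is fast enough to run on every frame.

## Stereo matching and measurement

The score `iou/θ` is singular at θ = 0, which is exactly the ideal
rectified case, so θ is floored at ε = 0.1°; the floor caps the score while
preserving its ordering. θ is measured in degrees — the unit rescales
scores but affects neither the gates nor the ranking. Default gates
θ_thresh = 5°, iou_thresh = 0.05 are deliberately permissive and
config-exposed. Assignment is greedy by descending score with deterministic
tie-breaks (lower left index, then right index); on randomized instances it
coincides with the exhaustive max-score assignment, which the tests verify.

Matching operates on undistorted-then-rectified corners (the rectified box
is the axis-aligned hull of the four mapped corners), because box overlap
between views is only meaningful after row alignment. Measurement
triangulates the four corner correspondences; distance is taken from the
triangulated box-center correspondence.

Two known limits, both inherent to box-overlap matching:

* A small animal close to the camera can have disparity larger than its own
  box width; the left/right boxes are then disjoint, the IoU gate fires,
  and no measurement is produced. With the default rig this affects roughly
  the closest-and-smallest tenth of a 100–500 mm / 0.5–2.0 m ensemble.
* Width/height are box-edge lengths, so they measure the projected extent:
  an animal oblique to the image plane is underestimated. No 3D pose
  correction is attempted.

The end-to-end recovery test (200 seeded single-fish events, 0.5 px box
jitter) asserts a median absolute width error within 2% and that the far
distance bin is worse than the near bin; a companion test at fixed 300 mm
length asserts strictly increasing error across 0.5/1.0/1.5/2.0 m bins,
where the 1/length confound is absent.

## Checkerboard validation

For each stereo image of the board, all same-row and same-column corner
pairs (every index gap k ≥ 1, not only adjacent corners) are triangulated
and compared against k × 50 mm; per-image horizontal and vertical means
weight all pairs uniformly. Images with fewer than two stereo-visible
corners are skipped. A full 8×7 grid yields 7·C(8,2) = 196 horizontal and
8·C(7,2) = 168 vertical pairs. Binned against mean corner distance, the
error reproduces the expected z²/(f·B) growth; the tests assert the
monotone trend, not absolute values, which depend on corner-detection noise
that is injected synthetically here.

## Detection post-processing and evaluation

NMS is class-agnostic and greedy by descending confidence, discarding boxes
whose IoU with a kept box strictly exceeds the threshold (default 0.6 —
overlap *at* the threshold survives). Evaluation matches detections to
ground truth greedily by confidence, one-to-one per frame, at IoU ≥ 0.5.
AP uses all-point (continuous) interpolation, which is exact and
oracle-checkable, rather than 11/101-point sampling. The F1/PR curves are
evaluated on a 0–1 confidence grid with step 0.005.

The confusion matrix is built in two passes: a class-aware pass fills the
diagonal, then a class-agnostic pass over the leftovers attributes
cross-class cells; remaining unmatched ground truth goes to the background
column (misses) and unmatched detections to the background row (false
positives). Since the matrix's matching rule is a design choice, both
row-normalized and column-normalized views are emitted alongside raw
counts; raw rows always sum to the per-class ground-truth totals. The
confusion matrix is thresholded at confidence 0.25 by default
(configurable); PR/AP always use the full score range.

## MaxN and aggregation

MaxN per species per activity sequence is the maximum single-frame count,
with the earliest frame on ties. Counts default to the left camera stream;
counting only stereo-matched pairs is available as an option but discards
monocular detections. Aggregation sums sequence MaxN values over hours,
days, or fixed frame blocks; a sequence belongs to the interval containing
its start frame (a deterministic boundary rule), and totals are conserved
by construction. An animal re-entering in a later sequence is counted anew
— without re-identification the statistic is deliberately conservative
within sequences and potentially over-counting across them.

## Manifest handling

The VIAME-style CSV reader groups rows into per-animal tracks, rejects
malformed rows and duplicate (track, frame) pairs with line numbers, and
derives day metadata from path-style image identifiers. Manifest summaries
count, per class, the images containing the class, boxes, and tracks;
distinct-image totals can be below the per-class column sum because one
image may host several classes — only box and track totals are exactly
summable, and the reference ten-taxon manifest shipped for cross-checking
sums to 92,899 boxes and 1198 tracks (76,658 / 16,241 boxes across its
train/validation split). The per-image split samples images, never boxes,
so all annotations of an image land in one set; holdout days are forced
into validation first, then random sampling fills training to the 0.85
ratio. Background (annotation-free) images can be carried as first-class
entries so training sets may include negatives.

## Problem sizes

Test and acceptance runs use deliberately small instances — 1000-point
geometry ensembles, 50 boards per distance bin, 200 single-fish events,
128×96 rendered clips of ~40 frames — chosen so the full suite completes in
well under a minute while keeping Monte-Carlo assertions (e.g. the 7%
label-swap recovery at n = 5000, ±0.01) statistically meaningful.
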