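"""Synthetic calibrated stereo scenes for pipeline development and testing.

Emulates the recording conditions of a stationary low-light underwater stereo
observatory: a two-camera rig with a 120 mm baseline and 1280x1024 monochrome
sensors at up to 20 fps, a 9x8-square / 50 mm checkerboard used for in-situ
calibration checks, and free-swimming fish/jellyfish targets that produce
per-camera bounding boxes. Detection noise (corner jitter, dropouts, false
positives, class confusion, confidence scores) is applied on top of exact
projected ground truth, so every emitted detection is traceable.

All randomness flows through a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import BoundingBox, Detection
from .geometry import (CameraIntrinsics, StereoRig, project_points, rodrigues)

__all__ = [
    "DEFAULT_CLASSES",
    "TargetSpec",
    "NoiseSpec",
    "SceneConfig",
    "GroundTruth",
    "make_rig",
    "make_camera",
    "project_checkerboard",
    "simulate_fish_scene",
    "render_frames",
]

# The ten-taxon vocabulary of the Baltic-Sea observatory dataset the
# generator emulates (four jellyfish categories dominate, six fish classes).
DEFAULT_CLASSES = [
    "Ctenophora",
    "Aurelia aurita",
    "Cyanea capillata",
    "Gadus morhua",
    "Fish unspecified",
    "Clupeidae",
    "Jellyfish unspecified",
    "Salmonidae",
    "Scomber scombrus",
    "Pleuronectoidei",
]


def make_camera(focal_px: float = 1400.0, image_size=(1280, 1024),
                distortion=None) -> CameraIntrinsics:
    """A camera with the principal point at the image center."""
    d = np.zeros(5) if distortion is None else np.asarray(distortion, dtype=float)
    return CameraIntrinsics(focal_px, focal_px,
                            image_size[0] / 2.0, image_size[1] / 2.0,
                            k1=d[0], k2=d[1], p1=d[2], p2=d[3], k3=d[4])


def make_rig(baseline_mm: float = 120.0, focal_px: float = 1400.0,
             image_size=(1280, 1024), distortion=None,
             yaw_deg: float = 0.0, pitch_deg: float = 0.0,
             roll_deg: float = 0.0) -> StereoRig:
    """Build a virtual stereo rig, right camera at +x by ``baseline_mm``.

    Optional yaw/pitch/roll angles misalign the right camera relative to the
    left (rotations about the y, x and z axes respectively, in degrees).
    """
    if baseline_mm <= 0:
        raise ValueError("baseline must be positive")
    cam = make_camera(focal_px, image_size, distortion)
    R = (rodrigues([0, 0, math.radians(roll_deg)])
         @ rodrigues([math.radians(pitch_deg), 0, 0])
         @ rodrigues([0, math.radians(yaw_deg), 0]))
    C = np.array([baseline_mm, 0.0, 0.0])
    return StereoRig(left=cam, right=cam, rotation=R, translation=-R @ C)


# ---------------------------------------------------------------------------
# Checkerboard

def checkerboard_corners_3d(pattern=(9, 8), square_mm: float = 50.0,
                            position=(0.0, 0.0, 1000.0),
                            rotation_deg=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Inner-corner grid of a checkerboard posed in the left-camera frame.

    A board of ``pattern`` = (squares_x, squares_y) squares has
    (squares_x - 1) x (squares_y - 1) inner corners. Returned as an
    (ny, nx, 3) array in mm, board centered at ``position`` after applying
    the (x, y, z)-axis rotations in degrees.
    """
    nx, ny = pattern[0] - 1, pattern[1] - 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * square_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * square_mm
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx, gy, np.zeros_like(gx)], axis=-1)
    rx, ry, rz = (math.radians(a) for a in rotation_deg)
    R = rodrigues([0, 0, rz]) @ rodrigues([0, ry, 0]) @ rodrigues([rx, 0, 0])
    return pts @ R.T + np.asarray(position, dtype=float)


def project_checkerboard(rig: StereoRig, position=(0.0, 0.0, 1000.0),
                         rotation_deg=(0.0, 0.0, 0.0), pattern=(9, 8),
                         square_mm: float = 50.0, noise_sigma: float = 0.0,
                         seed: int | None = None, image_size=None):
    """Project a posed checkerboard into both cameras.

    Returns ``(corners3d, left_px, right_px)`` where the pixel arrays have
    shape (ny, nx, 2) with i.i.d. Gaussian noise of ``noise_sigma`` px added
    per coordinate. Corners falling outside ``image_size`` (when given) are
    set to NaN (unobserved). Raises ``ValueError`` if the whole board lies
    behind either camera.
    """
    pts = checkerboard_corners_3d(pattern, square_mm, position, rotation_deg)
    shape = pts.shape[:2]
    flat = pts.reshape(-1, 3)
    in_right = flat @ rig.rotation.T + rig.translation
    if np.all(flat[:, 2] <= 0) or np.all(in_right[:, 2] <= 0):
        raise ValueError("checkerboard entirely behind a camera")
    rng = np.random.default_rng(seed)

    def _proj(cam, Rr=None, t=None):
        out = np.full((flat.shape[0], 2), np.nan)
        z = flat[:, 2] if Rr is None else in_right[:, 2]
        ok = z > 0
        if ok.any():
            out[ok] = project_points(cam, flat[ok], Rr, t)
        if noise_sigma > 0:
            out = out + rng.normal(0.0, noise_sigma, out.shape)
        if image_size is not None:
            w, h = image_size
            inside = ((out[:, 0] >= 0) & (out[:, 0] < w)
                      & (out[:, 1] >= 0) & (out[:, 1] < h))
            out[~inside] = np.nan
        return out.reshape(*shape, 2)

    left = _proj(rig.left)
    right = _proj(rig.right, rig.rotation, rig.translation)
    return pts, left, right


# ---------------------------------------------------------------------------
# Fish / jellyfish scenes

# Unit directions used to sample the silhouette of an ellipsoidal target:
# the 26 nonzero sign combinations of a 3x3x3 lattice, normalized.
_DIRS = np.array([v for v in
                  ((i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1)) if any(v)], dtype=float)
_DIRS /= np.linalg.norm(_DIRS, axis=1, keepdims=True)


@dataclass(frozen=True)
class TargetSpec:
    """One simulated animal: an ellipsoid following piecewise-linear waypoints.

    ``length_mm`` spans the x-extent (body length), ``height_mm`` the
    y-extent, ``width_mm`` the z-extent (defaults to height). ``waypoints``
    are (frame, x, y, z) rows in mm, left-camera frame; position is linearly
    interpolated between them, and the target exists on
    [first frame, last frame].
    """

    label: str
    length_mm: float
    height_mm: float
    waypoints: tuple  # ((frame, x, y, z), ...)
    width_mm: float | None = None
    track_id: int = 0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.height_mm <= 0:
            raise ValueError("target dimensions must be positive")

    @property
    def frame_span(self) -> tuple[int, int]:
        fr = [int(w[0]) for w in self.waypoints]
        return min(fr), max(fr)

    def position(self, frame: int) -> np.ndarray:
        wp = np.asarray(self.waypoints, dtype=float)
        return np.array([np.interp(frame, wp[:, 0], wp[:, 1 + a])
                         for a in range(3)])

    def surface_points(self, frame: int) -> np.ndarray:
        semi = np.array([self.length_mm / 2.0, self.height_mm / 2.0,
                         (self.width_mm or self.height_mm) / 2.0])
        return self.position(frame) + _DIRS * semi


@dataclass(frozen=True)
class NoiseSpec:
    """Detection-noise model applied to projected ground-truth boxes."""

    jitter_px: float = 0.0          # Gaussian sigma per box-corner coordinate
    dropout_prob: float = 0.0       # per detection per camera
    false_positive_rate: float = 0.0  # expected per frame per camera
    class_confusion_prob: float = 0.0
    # confidence ~ Beta(a, b): sharp for true positives, diffuse for clutter
    tp_conf_beta: tuple = (8.0, 2.0)
    fp_conf_beta: tuple = (2.0, 5.0)

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.class_confusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic stereo scene."""

    rig: StereoRig
    image_size: tuple = (1280, 1024)
    targets: tuple = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_frames: int = 50
    fps: float = 20.0
    classes: tuple = tuple(DEFAULT_CLASSES)
    seed: int = 0
    stream_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image size must be at least 64x64")


@dataclass
class GroundTruth:
    """Exact projected boxes and per-target truth for one scene.

    ``boxes`` holds Detection objects (confidence 1.0) per frame/camera;
    ``track_of`` maps each of them to its target's track id; ``targets``
    retains the specs; ``distance_mm[(track_id, frame)]`` is the true
    camera-to-center distance.
    """

    boxes: list
    track_of: dict
    targets: list
    distance_mm: dict

    def boxes_for(self, frame: int, camera: str):
        return [d for d in self.boxes if d.frame == frame and d.camera == camera]

    def visibility(self, camera: str = "left") -> dict:
        """track id -> sorted list of frames where the target is visible."""
        vis: dict = {}
        for d in self.boxes:
            if d.camera == camera:
                vis.setdefault(self.track_of[id(d)], []).append(d.frame)
        return {k: sorted(v) for k, v in vis.items()}


def _project_box(cam, pts, image_size, rotation=None, translation=None):
    """Axis-aligned hull of projected surface points, clipped to the image.

    Returns None when the target is behind the camera or projects outside.
    """
    P = pts if rotation is None else pts @ np.asarray(rotation).T + translation
    if np.any(P[:, 2] <= 0):
        return None
    uv = project_points(cam, pts, rotation, translation)
    x1, y1 = uv.min(axis=0)
    x2, y2 = uv.max(axis=0)
    w, h = image_size
    x1, x2 = max(x1, 0.0), min(x2, float(w))
    y1, y2 = max(y1, 0.0), min(y2, float(h))
    if x2 - x1 < 1e-6 or y2 - y1 < 1e-6:
        return None
    return BoundingBox(x1, y1, x2, y2)


def simulate_fish_scene(config: SceneConfig):
    """Generate exact ground truth and a noisy detection stream.

    Ground-truth boxes are the image-axis-aligned hulls of 26 sampled
    extremal points of each ellipsoidal target. Noise is applied after
    projection: corner jitter, per-detection dropout, Poisson false
    positives with random labels, and label confusion; confidences are
    Beta-distributed (sharp for true positives, diffuse for clutter).

    Returns ``(GroundTruth, detections)``; detections are sorted by
    (frame, camera, x1).
    """
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    gt_boxes: list = []
    track_of: dict = {}
    distance: dict = {}
    detections: list = []
    classes = list(config.classes)

    for frame in range(config.n_frames):
        for cam_name in ("left", "right"):
            cam = config.rig.left if cam_name == "left" else config.rig.right
            Rr = None if cam_name == "left" else config.rig.rotation
            t = None if cam_name == "left" else config.rig.translation
            for tgt in config.targets:
                f0, f1 = tgt.frame_span
                if not f0 <= frame <= f1:
                    continue
                box = _project_box(cam, tgt.surface_points(frame),
                                   config.image_size, Rr, t)
                if box is None:
                    continue
                det = Detection(frame=frame, camera=cam_name, box=box,
                                label=tgt.label, confidence=1.0,
                                stream_id=config.stream_id)
                gt_boxes.append(det)
                track_of[id(det)] = tgt.track_id
                if cam_name == "left":
                    distance[(tgt.track_id, frame)] = float(
                        np.linalg.norm(tgt.position(frame)))
                # noisy counterpart
                if rng.random() < noise.dropout_prob:
                    continue
                label = tgt.label
                if noise.class_confusion_prob > 0 and rng.random() < noise.class_confusion_prob:
                    others = [c for c in classes if c != label]
                    label = others[rng.integers(len(others))]
                c = box.corners() + (rng.normal(0.0, noise.jitter_px, (4, 2))
                                     if noise.jitter_px > 0 else 0.0)
                x1, y1 = c.min(axis=0)
                x2, y2 = c.max(axis=0)
                if x2 - x1 < 1e-6 or y2 - y1 < 1e-6:
                    continue
                conf = float(np.clip(rng.beta(*noise.tp_conf_beta), 0.0, 1.0))
                detections.append(Detection(frame=frame, camera=cam_name,
                                            box=BoundingBox(x1, y1, x2, y2),
                                            label=label, confidence=conf,
                                            stream_id=config.stream_id))
            # false positives
            if noise.false_positive_rate > 0:
                for _ in range(rng.poisson(noise.false_positive_rate)):
                    w_img, h_img = config.image_size
                    bw = rng.uniform(10, w_img / 4)
                    bh = rng.uniform(10, h_img / 4)
                    x1 = rng.uniform(0, w_img - bw)
                    y1 = rng.uniform(0, h_img - bh)
                    label = classes[rng.integers(len(classes))]
                    conf = float(np.clip(rng.beta(*noise.fp_conf_beta), 0.0, 1.0))
                    detections.append(Detection(
                        frame=frame, camera=cam_name,
                        box=BoundingBox(x1, y1, x1 + bw, y1 + bh),
                        label=label, confidence=conf,
                        stream_id=config.stream_id))

    detections.sort(key=lambda d: (d.frame, d.camera, d.box.x1))
    gt = GroundTruth(boxes=gt_boxes, track_of=track_of,
                     targets=list(config.targets), distance_mm=distance)
    return gt, detections


def render_frames(config: SceneConfig, background_level: float = 80.0,
                  background_noise: float = 2.0, target_intensity: float = 180.0,
                  camera: str = "left") -> np.ndarray:
    """Render monochrome frames of a scene for one camera.

    Targets are drawn as filled ellipses inscribed in their ground-truth
    boxes over a static background (fixed spatial pattern) plus per-frame
    Gaussian sensor noise. Returns a (n_frames, height, width) uint8 array;
    deterministic given the scene seed.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(config.seed + 1)
    w, h = config.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    static = background_level + 10.0 * np.sin(xx / 37.0) * np.cos(yy / 53.0)
    gt, _ = simulate_fish_scene(config)
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    for f in range(config.n_frames):
        img = static + rng.normal(0.0, background_noise, (h, w))
        for det in gt.boxes_for(f, camera):
            b = det.box
            cy, cx = (b.y1 + b.y2) / 2.0, (b.x1 + b.x2) / 2.0
            rr, cc = draw_ellipse(cy, cx, max(b.height / 2.0, 1.0),
                                  max(b.width / 2.0, 1.0), shape=(h, w))
            img[rr, cc] = target_intensity
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)
    return frames
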