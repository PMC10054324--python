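"""Bounding-box stereo correspondence and metric measurement.

After rectification, the two views of an animal lie on (nearly) the same
image row, so candidate box pairs can be scored with a simple geometric
criterion: the score is the box overlap (IoU) divided by the angle θ between
the horizontal axis and the line joining the box centers,

    mscore(box1, box2) = 0        if θ > θ_thresh, iou < iou_thresh,
                                  or the predicted classes differ,
                         iou / θ  otherwise,

with θ in degrees and a small floor ε guarding the θ -> 0 singularity of the
ideally rectified case. When several animals share an epipolar line, matches
are accepted greedily by descending score, one-to-one. Matched box corners
are then triangulated to yield the animal's distance and its width/height in
real-world millimetres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .detection import BoundingBox, Detection, iou
from .geometry import RectifiedRig, triangulate

logger = logging.getLogger(__name__)

__all__ = [
    "MatchConfig",
    "StereoMatch",
    "Measurement",
    "MeasurementRejected",
    "match_score",
    "match_detections",
    "rectify_detection",
    "measure",
]


@dataclass(frozen=True)
class MatchConfig:
    """Gates and numerical guards for the box matching score.

    theta_thresh_deg : maximum allowed angle of the center line from the
        horizontal (residual epipolar misalignment).
    iou_thresh : minimum box overlap.
    epsilon_deg : floor for θ in the score denominator.
    require_class_equality : reject pairs whose predicted species differ.
    """

    theta_thresh_deg: float = 5.0
    iou_thresh: float = 0.05
    epsilon_deg: float = 0.1
    require_class_equality: bool = True

    def __post_init__(self) -> None:
        if self.theta_thresh_deg <= 0 or self.epsilon_deg <= 0:
            raise ValueError("angle parameters must be positive")
        if not 0.0 <= self.iou_thresh <= 1.0:
            raise ValueError("iou_thresh must lie in [0, 1]")


@dataclass(frozen=True)
class StereoMatch:
    """A matched left/right detection pair with its score diagnostics."""

    left: Detection
    right: Detection
    score: float
    theta_deg: float
    iou: float


@dataclass(frozen=True)
class Measurement:
    """Metric measurement of one matched animal."""

    label: str
    frame: int
    distance_mm: float
    width_mm: float
    height_mm: float
    corners3d: np.ndarray  # (4, 3): TL, TR, BL, BR in the left-camera frame
    match: StereoMatch


class MeasurementRejected(ValueError):
    """Raised when a match cannot be measured (e.g. non-positive disparity)."""


def center_angle_deg(box_left: BoundingBox, box_right: BoundingBox) -> float:
    """|angle| in degrees between the horizontal and the center-center line."""
    (x1, y1), (x2, y2) = box_left.center, box_right.center
    return abs(math.degrees(math.atan2(y2 - y1, x2 - x1)))


def match_score(box_left: BoundingBox, box_right: BoundingBox,
                class_left: str, class_right: str,
                config: MatchConfig | None = None) -> tuple[float, float, float]:
    """Score one candidate pair; returns ``(score, theta_deg, iou)``.

    The score is 0 under any gate (class mismatch, θ above threshold, IoU
    below threshold) and ``iou / max(θ, ε)`` otherwise.
    """
    config = config or MatchConfig()
    theta = center_angle_deg(box_left, box_right)
    theta = min(theta, 180.0 - theta)  # angle from the horizontal axis
    overlap = iou(box_left, box_right)
    if config.require_class_equality and class_left != class_right:
        return 0.0, theta, overlap
    if theta > config.theta_thresh_deg or overlap < config.iou_thresh:
        return 0.0, theta, overlap
    return overlap / max(theta, config.epsilon_deg), theta, overlap


def rectify_detection(det: Detection, rect: RectifiedRig) -> Detection:
    """Map a raw-pixel detection into rectified coordinates.

    The four box corners are undistorted and rotated into the rectified
    frame; the rectified box is the axis-aligned hull of the mapped corners.
    """
    mapped = rect.raw_to_rectified(det.camera, det.box.corners())
    x1, y1 = mapped.min(axis=0)
    x2, y2 = mapped.max(axis=0)
    return Detection(frame=det.frame, camera=det.camera,
                     box=BoundingBox(x1, y1, x2, y2), label=det.label,
                     confidence=det.confidence, stream_id=det.stream_id)


def match_detections(left, right, config: MatchConfig | None = None):
    """Match detections of one synchronized, rectified frame pair.

    Scores every cross pair, then accepts matches greedily by descending
    score with one-to-one use of each detection; zero-score pairs are never
    matched. Ties break on the lower (left index, right index). Returns
    ``(matches, unmatched_left, unmatched_right)``.
    """
    config = config or MatchConfig()
    left = list(left)
    right = list(right)
    candidates = []
    for i, dl in enumerate(left):
        for j, dr in enumerate(right):
            s, theta, overlap = match_score(dl.box, dr.box, dl.label, dr.label,
                                            config)
            if s > 0:
                candidates.append((s, i, j, theta, overlap))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_l: set = set()
    used_r: set = set()
    matches = []
    for s, i, j, theta, overlap in candidates:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        matches.append(StereoMatch(left=left[i], right=right[j], score=s,
                                   theta_deg=theta, iou=overlap))
    unmatched_l = [d for i, d in enumerate(left) if i not in used_l]
    unmatched_r = [d for j, d in enumerate(right) if j not in used_r]
    return matches, unmatched_l, unmatched_r


def measure(match: StereoMatch, rect: RectifiedRig) -> Measurement:
    """Triangulate a matched pair's box corners into a metric measurement.

    The four corner correspondences (top-left to top-left, etc.) are
    triangulated; width is the mean 3D length of the top and bottom box
    edges, height the mean of the left and right edges, and distance the
    Euclidean norm of the triangulated box-center point.

    Raises
    ------
    MeasurementRejected
        If any corner correspondence has non-positive disparity or a box is
        degenerate.
    """
    cl = match.left.box.corners()
    cr = match.right.box.corners()
    centers = np.vstack([match.left.box.center, match.right.box.center])
    try:
        pts = triangulate(rect, cl, cr)
        center3d = triangulate(rect, centers[0], centers[1])
    except ValueError as exc:
        logger.info("measurement rejected for frame %d (%s): %s",
                    match.left.frame, match.left.label, exc)
        raise MeasurementRejected(str(exc)) from exc
    tl, tr, bl, br = pts
    width = 0.5 * (np.linalg.norm(tr - tl) + np.linalg.norm(br - bl))
    height = 0.5 * (np.linalg.norm(bl - tl) + np.linalg.norm(br - tr))
    return Measurement(label=match.left.label, frame=match.left.frame,
                       distance_mm=float(np.linalg.norm(center3d)),
                       width_mm=float(width), height_mm=float(height),
                       corners3d=pts, match=match)
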