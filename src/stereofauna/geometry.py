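"""Camera geometry for a calibrated underwater stereo rig.

The metric backbone of the pipeline: a pinhole camera model extended with
Brown–Conrady radial/tangential lens distortion, stereo rectification into a
row-aligned virtual rig, disparity triangulation, and reprojection error.

Conventions
-----------
* Pixel origin at the top-left corner, x to the right, y down; continuous
  coordinates refer to pixel centers.
* 3D coordinates are in millimetres in the *left* camera frame: z forward
  (optical axis), x right, y down.
* Extrinsics follow the ``X_right = R @ X_left + t`` convention, so the right
  camera center expressed in the left frame is ``C = -R.T @ t``.

Refraction by the flat housing port is not modelled explicitly; for an
in-situ-calibrated rig it is absorbed into the intrinsic and distortion
parameters, at the cost of a small systematic error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "RectifiedRig",
    "NonProjectablePointError",
    "UndistortDivergenceError",
    "project_point",
    "project_points",
    "undistort_points",
    "distort_normalized",
    "rectify",
    "triangulate",
    "reprojection_error",
    "rodrigues",
    "load_calibration",
    "save_calibration",
]


class NonProjectablePointError(ValueError):
    """Raised when a point at or behind the optical center is projected."""


class UndistortDivergenceError(RuntimeError):
    """Raised when iterative undistortion fails to converge (out-of-model pixel)."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics plus Brown–Conrady distortion coefficients.

    Distortion uses radial terms ``k1, k2, k3`` and tangential ``p1, p2``
    (all dimensionless, applied in normalized image coordinates).
    """

    focal_x: float
    focal_y: float
    principal_x: float
    principal_y: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        if not (self.focal_x > 0 and self.focal_y > 0):
            raise ValueError("focal lengths must be positive")
        for name in ("k1", "k2", "p1", "p2", "k3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"distortion coefficient {name} must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 camera matrix K."""
        return np.array(
            [
                [self.focal_x, 0.0, self.principal_x],
                [0.0, self.focal_y, self.principal_y],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def distortion(self) -> np.ndarray:
        """Coefficients in (k1, k2, p1, p2, k3) order."""
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])

    @classmethod
    def from_matrix(cls, K: np.ndarray, dist=None) -> "CameraIntrinsics":
        K = np.asarray(K, dtype=float)
        d = np.zeros(5) if dist is None else np.asarray(dist, dtype=float).ravel()
        if d.size < 5:
            d = np.concatenate([d, np.zeros(5 - d.size)])
        return cls(K[0, 0], K[1, 1], K[0, 2], K[1, 2],
                   k1=d[0], k2=d[1], p1=d[2], p2=d[3], k3=d[4])


def rodrigues(vec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle (Rodrigues) 3-vector."""
    vec = np.asarray(vec, dtype=float).ravel()
    theta = float(np.linalg.norm(vec))
    if theta < 1e-15:
        return np.eye(3)
    k = vec / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9) * 10):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has negative determinant")
    return R


@dataclass(frozen=True)
class StereoRig:
    """A calibrated two-camera rig.

    ``rotation`` / ``translation`` map left-frame coordinates into the right
    camera frame: ``X_right = rotation @ X_left + translation`` (translation in
    mm). The default synthetic rig has a 120 mm baseline.
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).ravel()
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if np.linalg.norm(t) <= 0:
            raise ValueError("zero baseline: cameras are coincident")
        object.__setattr__(self, "translation", t)

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.translation))

    @property
    def right_center(self) -> np.ndarray:
        """Right camera center in the left frame."""
        return -self.rotation.T @ self.translation


def project_points(cam: CameraIntrinsics, points: np.ndarray,
                   rotation: np.ndarray | None = None,
                   translation: np.ndarray | None = None) -> np.ndarray:
    """Project 3D points (mm) to distorted pixel coordinates.

    Parameters
    ----------
    points : (n, 3) array in the reference (left) frame.
    rotation, translation : optional pose mapping reference frame to this
        camera's frame; identity/zero by default.

    Raises
    ------
    NonProjectablePointError
        If any point lies at or behind the optical center (z <= 0).
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if rotation is not None:
        P = P @ np.asarray(rotation).T
    if translation is not None:
        P = P + np.asarray(translation).ravel()
    z = P[:, 2]
    if np.any(z <= 0):
        raise NonProjectablePointError("point at or behind the optical center")
    xn = P[:, 0] / z
    yn = P[:, 1] / z
    xd, yd = distort_normalized(cam, xn, yn)
    return np.column_stack([cam.focal_x * xd + cam.principal_x,
                            cam.focal_y * yd + cam.principal_y])


def project_point(cam: CameraIntrinsics, point,
                  rotation=None, translation=None) -> tuple[float, float]:
    """Project a single 3D point; returns an (u, v) pixel pair."""
    uv = project_points(cam, np.asarray(point, dtype=float).reshape(1, 3),
                        rotation, translation)
    return float(uv[0, 0]), float(uv[0, 1])


def distort_normalized(cam: CameraIntrinsics, xn, yn):
    """Apply the Brown–Conrady distortion polynomial in normalized coords."""
    xn = np.asarray(xn, dtype=float)
    yn = np.asarray(yn, dtype=float)
    r2 = xn * xn + yn * yn
    radial = 1.0 + cam.k1 * r2 + cam.k2 * r2 * r2 + cam.k3 * r2 * r2 * r2
    xd = xn * radial + 2.0 * cam.p1 * xn * yn + cam.p2 * (r2 + 2.0 * xn * xn)
    yd = yn * radial + cam.p1 * (r2 + 2.0 * yn * yn) + 2.0 * cam.p2 * xn * yn
    return xd, yd


def undistort_points(cam: CameraIntrinsics, pixels: np.ndarray,
                     max_iter: int = 30, tol: float = 1e-13) -> np.ndarray:
    """Invert the distortion model; returns ideal (pinhole) pixel coordinates.

    Fixed-point iteration in normalized coordinates: starting from the
    distorted position, repeatedly subtract the modelled distortion offset.
    Converges for moderate distortion within the calibrated field of view.

    Raises
    ------
    UndistortDivergenceError
        If the iteration has not converged after ``max_iter`` rounds.
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    if not np.all(np.isfinite(px)):
        raise ValueError("pixel coordinates must be finite")
    xd = (px[:, 0] - cam.principal_x) / cam.focal_x
    yd = (px[:, 1] - cam.principal_y) / cam.focal_y
    x, y = xd.copy(), yd.copy()
    converged = False
    for _ in range(max_iter):
        dx, dy = distort_normalized(cam, x, y)
        x_new = xd - (dx - x)
        y_new = yd - (dy - y)
        step = np.max(np.hypot(x_new - x, y_new - y)) if x.size else 0.0
        x, y = x_new, y_new
        if step < tol:
            converged = True
            break
    if not converged and np.any(cam.distortion != 0):
        dx, dy = distort_normalized(cam, x, y)
        if np.max(np.hypot(dx - xd, dy - yd)) > 1e-6:
            raise UndistortDivergenceError(
                "undistortion did not converge; pixel outside the distortion model")
    out = np.column_stack([cam.focal_x * x + cam.principal_x,
                           cam.focal_y * y + cam.principal_y])
    return out if np.asarray(pixels).ndim > 1 else out[0]


@dataclass(frozen=True)
class RectifiedRig:
    """A virtually rotated rig whose epipolar lines are image rows.

    ``rect_rotation`` maps left-frame coordinates into the rectified frame; the
    rectified cameras share focal length ``focal``, principal point
    ``(principal_x, principal_y)`` and are separated by ``baseline_mm`` along
    the rectified x-axis, so a scene point projects onto the same row in both
    images and its column difference (disparity) encodes depth.
    """

    rig: StereoRig
    rect_rotation: np.ndarray  # left-frame -> rectified frame
    focal: float
    principal_x: float
    principal_y: float
    baseline_mm: float
    epipolar_tol_px: float = 2.0

    @property
    def rot_left(self) -> np.ndarray:
        """Rotation applied to left-camera coordinates."""
        return self.rect_rotation

    @property
    def rot_right(self) -> np.ndarray:
        """Rotation applied to right-camera coordinates."""
        return self.rect_rotation @ self.rig.rotation.T

    def _cam_and_rot(self, camera: str):
        if camera == "left":
            return self.rig.left, self.rot_left
        if camera == "right":
            return self.rig.right, self.rot_right
        raise ValueError(f"unknown camera {camera!r}")

    def raw_to_rectified(self, camera: str, pixels: np.ndarray) -> np.ndarray:
        """Map raw (distorted) pixels of one camera into rectified pixels."""
        cam, Rr = self._cam_and_rot(camera)
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        und = np.atleast_2d(undistort_points(cam, px))
        xn = (und[:, 0] - cam.principal_x) / cam.focal_x
        yn = (und[:, 1] - cam.principal_y) / cam.focal_y
        rays = np.column_stack([xn, yn, np.ones_like(xn)]) @ Rr.T
        out = np.column_stack([
            self.focal * rays[:, 0] / rays[:, 2] + self.principal_x,
            self.focal * rays[:, 1] / rays[:, 2] + self.principal_y,
        ])
        return out if np.asarray(pixels).ndim > 1 else out[0]

    def rectified_to_raw(self, camera: str, pixels: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`raw_to_rectified` (used for image warping)."""
        cam, Rr = self._cam_and_rot(camera)
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        xn = (px[:, 0] - self.principal_x) / self.focal
        yn = (px[:, 1] - self.principal_y) / self.focal
        rays = np.column_stack([xn, yn, np.ones_like(xn)]) @ Rr
        xd, yd = distort_normalized(cam, rays[:, 0] / rays[:, 2],
                                    rays[:, 1] / rays[:, 2])
        out = np.column_stack([cam.focal_x * xd + cam.principal_x,
                               cam.focal_y * yd + cam.principal_y])
        return out if np.asarray(pixels).ndim > 1 else out[0]

    def project(self, camera: str, points: np.ndarray) -> np.ndarray:
        """Project left-frame 3D points through a rectified (ideal) camera."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        X = P @ self.rect_rotation.T
        if camera == "right":
            X = X - np.array([self.baseline_mm, 0.0, 0.0])
        elif camera != "left":
            raise ValueError(f"unknown camera {camera!r}")
        z = X[:, 2]
        if np.any(z <= 0):
            raise NonProjectablePointError("point behind the rectified camera")
        return np.column_stack([self.focal * X[:, 0] / z + self.principal_x,
                                self.focal * X[:, 1] / z + self.principal_y])


def rectify(rig: StereoRig, epipolar_tol_px: float = 2.0) -> RectifiedRig:
    """Build the row-aligned virtual rig for a calibrated stereo pair.

    The rectified x-axis is taken along the inter-camera baseline, the y-axis
    as close as possible to the original left-camera y-axis, and both virtual
    cameras share the mean focal length and principal point of the pair.
    """
    C = rig.right_center
    b = np.linalg.norm(C)
    if b <= 0:
        raise ValueError("degenerate rig: zero baseline")
    e1 = C / b
    z_axis = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(z_axis, e1)
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        raise ValueError("degenerate rig: baseline parallel to optical axis")
    e2 = e2 / n2
    e3 = np.cross(e1, e2)
    R_rect = np.vstack([e1, e2, e3])  # rows: new axes in left-frame coords
    focal = float(np.mean([rig.left.focal_x, rig.left.focal_y,
                           rig.right.focal_x, rig.right.focal_y]))
    cx = float(np.mean([rig.left.principal_x, rig.right.principal_x]))
    cy = float(np.mean([rig.left.principal_y, rig.right.principal_y]))
    return RectifiedRig(rig=rig, rect_rotation=R_rect, focal=focal,
                        principal_x=cx, principal_y=cy, baseline_mm=float(b),
                        epipolar_tol_px=epipolar_tol_px)


def triangulate(rect: RectifiedRig, pixel_left, pixel_right) -> np.ndarray:
    """Triangulate rectified pixel correspondences into left-frame 3D (mm).

    Depth follows the rectified stereo relation ``z = focal * baseline / d``
    with disparity ``d = col_left - col_right``. Row disagreement beyond
    ``rect.epipolar_tol_px`` is logged as a warning; rows are averaged.

    Accepts single pairs or (n, 2) arrays. Raises ``ValueError`` for
    non-positive disparity (a point at infinity or a matching error).
    """
    pl = np.atleast_2d(np.asarray(pixel_left, dtype=float))
    pr = np.atleast_2d(np.asarray(pixel_right, dtype=float))
    if pl.shape != pr.shape:
        raise ValueError("left/right pixel arrays must have equal shape")
    disparity = pl[:, 0] - pr[:, 0]
    if np.any(disparity <= 0):
        raise ValueError("non-positive disparity: point at infinity or bad match")
    drow = np.abs(pl[:, 1] - pr[:, 1])
    if np.any(drow > rect.epipolar_tol_px):
        logger.warning("epipolar row disagreement up to %.3f px exceeds tolerance %.3f",
                       float(drow.max()), rect.epipolar_tol_px)
    z = rect.focal * rect.baseline_mm / disparity
    row = 0.5 * (pl[:, 1] + pr[:, 1])
    x = (pl[:, 0] - rect.principal_x) * z / rect.focal
    y = (row - rect.principal_y) * z / rect.focal
    X_rect = np.column_stack([x, y, z])
    X_left = X_rect @ rect.rect_rotation  # == (R_rect.T @ X_rect.T).T
    return X_left if np.asarray(pixel_left).ndim > 1 else X_left[0]


def reprojection_error(cam: CameraIntrinsics, points3d: np.ndarray,
                       observations: np.ndarray,
                       rotation=None, translation=None) -> float:
    """Mean Euclidean pixel distance between projections and observations."""
    P = np.atleast_2d(np.asarray(points3d, dtype=float))
    O = np.atleast_2d(np.asarray(observations, dtype=float))
    if P.shape[0] == 0:
        raise ValueError("no points to evaluate")
    if P.shape[0] != O.shape[0]:
        raise ValueError("points and observations must have equal length")
    proj = project_points(cam, P, rotation, translation)
    return float(np.mean(np.linalg.norm(proj - O, axis=1)))


# ---------------------------------------------------------------------------
# Calibration file I/O

def _cam_to_dict(cam: CameraIntrinsics) -> dict:
    return {"camera_matrix": cam.matrix.tolist(),
            "distortion": cam.distortion.tolist()}


def _cam_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics.from_matrix(np.asarray(d["camera_matrix"], dtype=float),
                                        d.get("distortion"))


def save_calibration(rig: StereoRig, path) -> None:
    """Write a rig to YAML (or JSON when the suffix is .json)."""
    payload = {
        "left": _cam_to_dict(rig.left),
        "right": _cam_to_dict(rig.right),
        "rotation": rig.rotation.tolist(),
        "translation_mm": rig.translation.tolist(),
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_calibration(path) -> StereoRig:
    """Read a rig from a YAML/JSON calibration file and validate invariants.

    ``rotation`` may be a 3x3 matrix or a Rodrigues 3-vector; translation is
    in millimetres.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    R = np.asarray(data["rotation"], dtype=float)
    if R.size == 3:
        R = rodrigues(R)
    return StereoRig(left=_cam_from_dict(data["left"]),
                     right=_cam_from_dict(data["right"]),
                     rotation=R,
                     translation=np.asarray(data["translation_mm"], dtype=float))
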