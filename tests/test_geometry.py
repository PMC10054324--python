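"""Camera model, rectification and triangulation."""

import math

import numpy as np
import pytest

from stereofauna import geometry, synthetic
from stereofauna.geometry import (CameraIntrinsics, NonProjectablePointError,
                                  StereoRig, load_calibration, project_point,
                                  project_points, rectify,
                                  reprojection_error, save_calibration,
                                  triangulate, undistort_points)

from conftest import project_stereo

CAM = CameraIntrinsics(1400.0, 1400.0, 640.0, 512.0)
CAM_K1 = CameraIntrinsics(1400.0, 1400.0, 640.0, 512.0, k1=-0.1)


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        for z in (100.0, 1500.0, 4000.0):
            assert project_point(CAM_K1, (0, 0, z)) == (640.0, 512.0)

    def test_pinhole_identity_without_distortion(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform([-500, -400, 300], [500, 400, 4000], (50, 3))
        uv = project_points(CAM, pts)
        expected = np.column_stack([
            1400.0 * pts[:, 0] / pts[:, 2] + 640.0,
            1400.0 * pts[:, 1] / pts[:, 2] + 512.0])
        np.testing.assert_allclose(uv, expected, atol=1e-12)

    def test_radial_distortion_matches_direct_polynomial(self):
        # independent evaluation of the k1-only radial model
        p = (300.0, -200.0, 1000.0)
        xn, yn = p[0] / p[2], p[1] / p[2]
        r2 = xn**2 + yn**2
        factor = 1.0 - 0.1 * r2
        expected = (1400.0 * xn * factor + 640.0, 1400.0 * yn * factor + 512.0)
        assert project_point(CAM_K1, p) == pytest.approx(expected, abs=1e-12)

    def test_point_behind_camera_rejected(self):
        with pytest.raises(NonProjectablePointError):
            project_point(CAM, (0, 0, -5.0))
        with pytest.raises(NonProjectablePointError):
            project_point(CAM, (10.0, 0, 0.0))


class TestUndistort:
    def test_zero_distortion_is_identity(self):
        px = np.array([[100.0, 900.0], [640.0, 512.0], [13.5, 1000.25]])
        np.testing.assert_allclose(undistort_points(CAM, px), px, atol=1e-12)

    def test_round_trip_recovers_pinhole_projection(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform([-400, -300, 500], [400, 300, 3000], (200, 3))
        distorted = project_points(CAM_K1, pts)
        undone = undistort_points(CAM_K1, distorted)
        pinhole = project_points(CAM, pts)
        np.testing.assert_allclose(undone, pinhole, atol=1e-6)

    def test_principal_point_fixed_for_any_coefficients(self):
        cam = CameraIntrinsics(1400, 1400, 640, 512, k1=0.3, k2=-0.1,
                               p1=0.01, p2=-0.02, k3=0.05)
        np.testing.assert_allclose(
            undistort_points(cam, np.array([[640.0, 512.0]])),
            [[640.0, 512.0]], atol=1e-12)


class TestRectification:
    def test_axis_aligned_rig_rectifies_to_identity(self, rig, rect):
        np.testing.assert_allclose(rect.rect_rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(rect.rot_right, np.eye(3), atol=1e-12)

    def test_yawed_rig_row_alignment(self, distorted_rig):
        rect = geometry.rectify(distorted_rig)
        rng = np.random.default_rng(2)
        pts = rng.uniform([-300, -300, 500], [300, 300, 3000], (100, 3))
        uvl, uvr = project_stereo(distorted_rig, pts)
        pl = rect.raw_to_rectified("left", uvl)
        pr = rect.raw_to_rectified("right", uvr)
        assert np.abs(pl[:, 1] - pr[:, 1]).max() < 1e-6

    def test_disparity_positive_for_points_in_front(self, distorted_rig):
        rect = geometry.rectify(distorted_rig)
        rng = np.random.default_rng(3)
        pts = rng.uniform([-300, -300, 400], [300, 300, 5000], (100, 3))
        uvl, uvr = project_stereo(distorted_rig, pts)
        pl = rect.raw_to_rectified("left", uvl)
        pr = rect.raw_to_rectified("right", uvr)
        assert np.all(pl[:, 0] - pr[:, 0] > 0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            StereoRig(CAM, CAM, np.eye(3), np.zeros(3))


class TestTriangulation:
    def test_on_axis_point_depth_exact(self, rig, rect):
        P = np.array([[0.0, 0.0, 1500.0]])
        uvl, uvr = project_stereo(rig, P)
        X = triangulate(rect, rect.raw_to_rectified("left", uvl),
                        rect.raw_to_rectified("right", uvr))
        assert abs(X[0, 2] - 1500.0) < 1e-6

    def test_depth_inversely_proportional_to_disparity(self, rect):
        z1 = triangulate(rect, [700.0, 512.0], [650.0, 512.0])[2]
        z2 = triangulate(rect, [700.0, 512.0], [600.0, 512.0])[2]
        assert z2 == pytest.approx(z1 / 2.0)

    def test_nonpositive_disparity_rejected(self, rect):
        with pytest.raises(ValueError):
            triangulate(rect, [600.0, 512.0], [600.0, 512.0])
        with pytest.raises(ValueError):
            triangulate(rect, [600.0, 512.0], [700.0, 512.0])

    def test_checkerboard_square_spacing_recovered(self, rig, rect):
        # adjacent inner corners of a 50 mm board, noise-free
        pts, lp, rp = synthetic.project_checkerboard(rig, position=(0, 0, 1200))
        X = triangulate(rect,
                        rect.raw_to_rectified("left", lp.reshape(-1, 2)),
                        rect.raw_to_rectified("right", rp.reshape(-1, 2)))
        X = X.reshape(lp.shape[:2] + (3,))
        horiz = np.linalg.norm(np.diff(X, axis=1), axis=2)
        vert = np.linalg.norm(np.diff(X, axis=0), axis=2)
        np.testing.assert_allclose(horiz, 50.0, atol=1e-6)
        np.testing.assert_allclose(vert, 50.0, atol=1e-6)


class TestReprojectionError:
    def test_zero_for_exact_observations(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform([-300, -300, 500], [300, 300, 3000], (30, 3))
        obs = project_points(CAM_K1, pts)
        assert reprojection_error(CAM_K1, pts, obs) == 0.0

    def test_gaussian_noise_gives_rayleigh_mean(self):
        # isotropic sigma=1 pixel noise -> mean radial error sigma*sqrt(pi/2)
        rng = np.random.default_rng(5)
        pts = rng.uniform([-300, -300, 500], [300, 300, 3000], (10_000, 3))
        obs = project_points(CAM, pts) + rng.normal(0.0, 1.0, (10_000, 2))
        err = reprojection_error(CAM, pts, obs)
        assert err == pytest.approx(math.sqrt(math.pi / 2.0), rel=0.03)

    def test_single_offset_is_euclidean_distance(self):
        pts = np.array([[0.0, 0.0, 1000.0]])
        obs = project_points(CAM, pts) + np.array([[3.0, 4.0]])
        assert reprojection_error(CAM, pts, obs) == pytest.approx(5.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reprojection_error(CAM, np.empty((0, 3)), np.empty((0, 2)))


def two_ray_intersection(rig, uv_left, uv_right):
    """Independent oracle: least-squares intersection of the two view rays."""
    ul = undistort_points(rig.left, np.atleast_2d(uv_left))[0]
    ur = undistort_points(rig.right, np.atleast_2d(uv_right))[0]
    d1 = np.array([(ul[0] - rig.left.principal_x) / rig.left.focal_x,
                   (ul[1] - rig.left.principal_y) / rig.left.focal_y, 1.0])
    d2_cam = np.array([(ur[0] - rig.right.principal_x) / rig.right.focal_x,
                       (ur[1] - rig.right.principal_y) / rig.right.focal_y, 1.0])
    d2 = rig.rotation.T @ d2_cam
    p1 = np.zeros(3)
    p2 = rig.right_center
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for p, d in ((p1, d1), (p2, d2)):
        d = d / np.linalg.norm(d)
        M = np.eye(3) - np.outer(d, d)
        A += M
        b += M @ p
    return np.linalg.solve(A, b)


class TestGeometryInvariants:
    def test_project_triangulate_round_trip(self, distorted_rig):
        rigs = [synthetic.make_rig(), distorted_rig,
                synthetic.make_rig(baseline_mm=200, focal_px=900,
                                   pitch_deg=1.0,
                                   distortion=[0.05, -0.01, 0, 0, 0.002])]
        rng = np.random.default_rng(6)
        for rig in rigs:
            rect = geometry.rectify(rig)
            pts = rng.uniform([-300, -300, 300], [300, 300, 5000], (300, 3))
            uvl, uvr = project_stereo(rig, pts)
            X = triangulate(rect, rect.raw_to_rectified("left", uvl),
                            rect.raw_to_rectified("right", uvr))
            assert np.abs(X - pts).max() < 1e-6

    def test_triangulation_matches_two_ray_oracle(self, distorted_rig):
        rect = geometry.rectify(distorted_rig)
        rng = np.random.default_rng(7)
        pts = rng.uniform([-300, -300, 400], [300, 300, 3000], (50, 3))
        uvl, uvr = project_stereo(distorted_rig, pts)
        for i in range(len(pts)):
            oracle = two_ray_intersection(distorted_rig, uvl[i], uvr[i])
            X = triangulate(rect,
                            rect.raw_to_rectified("left", uvl[i]),
                            rect.raw_to_rectified("right", uvr[i]))
            np.testing.assert_allclose(X, oracle, atol=1e-6)

    def test_scale_equivariance(self):
        rig = synthetic.make_rig()
        s = 3.5
        rig_scaled = StereoRig(rig.left, rig.right, rig.rotation,
                               rig.translation * s)
        rect = geometry.rectify(rig)
        rect_s = geometry.rectify(rig_scaled)
        pts = np.array([[120.0, -40.0, 900.0], [-200.0, 80.0, 2500.0]])
        uvl, uvr = project_stereo(rig, pts)
        uvl_s, uvr_s = project_stereo(rig_scaled, pts * s)
        X = triangulate(rect, rect.raw_to_rectified("left", uvl),
                        rect.raw_to_rectified("right", uvr))
        X_s = triangulate(rect_s, rect_s.raw_to_rectified("left", uvl_s),
                          rect_s.raw_to_rectified("right", uvr_s))
        np.testing.assert_allclose(X_s, X * s, rtol=1e-9)


class TestCalibrationIO:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, tmp_path, distorted_rig, suffix):
        path = tmp_path / f"calib{suffix}"
        save_calibration(distorted_rig, path)
        loaded = load_calibration(path)
        np.testing.assert_array_equal(loaded.rotation, distorted_rig.rotation)
        np.testing.assert_array_equal(loaded.translation,
                                      distorted_rig.translation)
        assert loaded.left == distorted_rig.left
        assert loaded.right == distorted_rig.right

    def test_rodrigues_rotation_accepted(self, tmp_path):
        path = tmp_path / "calib.yaml"
        path.write_text("""
left:  {camera_matrix: [[1400, 0, 640], [0, 1400, 512], [0, 0, 1]], distortion: [0, 0, 0, 0, 0]}
right: {camera_matrix: [[1400, 0, 640], [0, 1400, 512], [0, 0, 1]], distortion: [0, 0, 0, 0, 0]}
rotation: [0.0, 0.0349066, 0.0]
translation_mm: [-120.0, 0.0, 0.0]
""")
        rig = load_calibration(path)
        angle = math.degrees(math.acos((np.trace(rig.rotation) - 1) / 2))
        assert angle == pytest.approx(2.0, abs=1e-4)
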