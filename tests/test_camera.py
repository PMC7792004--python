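"""Camera model, distortion, fundamental matrix, rectification, rays."""

import numpy as np
import pytest

import skinloc as sl
from skinloc.camera import (DegenerateGeometryError, undistort_points,
                            distort_normalized)

from conftest import make_translation_pair


def make_camera(dist=(0, 0, 0, 0, 0)):
    return sl.CameraModel(camera_id=1, focal=(800.0, 800.0),
                          principal_point=(319.5, 239.5),
                          distortion=np.array(dist, dtype=float))


def random_scene_points(rng, n=30):
    pts = rng.uniform(-20, 20, size=(n, 3))
    pts[:, 2] = rng.uniform(-2, 2, size=n)
    return pts


class TestCorrectIntrinsics:
    def test_zero_distortion_is_bitexact_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(48, 64), dtype=np.uint8)
        out = sl.correct_intrinsics(img, make_camera())
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, img)

    def test_constant_image_stays_constant_in_interior(self):
        img = np.full((60, 80), 137, dtype=np.uint8)
        cam = sl.CameraModel(camera_id=1, focal=(100.0, 100.0),
                             principal_point=(39.5, 29.5),
                             distortion=np.array([0.1, -0.02, 0.001, 0.001, 0.0]))
        out = sl.correct_intrinsics(img, cam)
        assert np.all(out[10:-10, 10:-10] == 137)

    def test_radial_displacement_matches_distortion_polynomial(self):
        # a bright pixel at distorted location d appears, after image
        # undistortion, at u = undistort(d): evaluate the map independently
        cam = sl.CameraModel(camera_id=1, focal=(300.0, 300.0),
                             principal_point=(47.5, 47.5),
                             distortion=np.array([0.3, 0.0, 0.0, 0.0, 0.0]))
        img = np.zeros((96, 96), dtype=np.uint8)
        d = (70, 60)  # (col, row), off-center
        img[d[1], d[0]] = 255
        out = sl.correct_intrinsics(img, cam)
        # independent closed-form inversion: iterate the radial polynomial
        xn = (d[0] - 47.5) / 300.0
        yn = (d[1] - 47.5) / 300.0
        x, y = xn, yn
        for _ in range(50):
            r2 = x * x + y * y
            x = xn / (1 + 0.3 * r2)
            y = yn / (1 + 0.3 * r2)
        expected = np.array([300.0 * x + 47.5, 300.0 * y + 47.5])
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert np.hypot(peak[1] - expected[0], peak[0] - expected[1]) <= 1.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            sl.correct_intrinsics(np.zeros((0, 0)), make_camera())

    def test_undistort_points_inverts_distortion(self):
        cam = make_camera(dist=(0.08, -0.01, 0.002, -0.001, 0.0))
        rng = np.random.default_rng(3)
        px = rng.uniform(100, 500, size=(40, 2))
        xn = (px[:, 0] - 319.5) / 800.0
        yn = (px[:, 1] - 239.5) / 800.0
        xd, yd = distort_normalized(xn, yn, cam.distortion)
        distorted = np.column_stack([800.0 * xd + 319.5, 800.0 * yd + 239.5])
        rec = undistort_points(distorted, cam)
        np.testing.assert_allclose(rec, px, atol=1e-6)


class TestFundamentalMatrix:
    def test_pure_translation_recovers_analytic_f(self):
        cams = make_translation_pair()
        rng = np.random.default_rng(1)
        pts = rng.uniform(-30, 30, size=(20, 3))
        pts[:, 2] += 400.0
        pi = cams[0].project(pts)
        pj = cams[1].project(pts)
        F = sl.estimate_fundamental(pi, pj).F
        expected = np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        expected /= np.linalg.norm(expected)
        # sign convention: compare up to the fixed normalization
        if np.sign(F[2, 1]) != np.sign(expected[2, 1]):
            F = -F
        assert np.max(np.abs(F - expected)) < 1e-6

    def test_noiseless_residuals_vanish(self, small_rig):
        rng = np.random.default_rng(2)
        pts = random_scene_points(rng)
        pi = small_rig[0].project(pts)
        pj = small_rig[1].project(pts)
        F = sl.estimate_fundamental(pi, pj)
        assert np.max(np.abs(F.residuals(pi, pj))) < 1e-6

    def test_rank_two_enforced(self, small_rig):
        rng = np.random.default_rng(4)
        pts = random_scene_points(rng)
        F = sl.estimate_fundamental(small_rig[0].project(pts),
                                    small_rig[1].project(pts))
        sv = np.linalg.svd(F.F, compute_uv=False)
        assert sv[0] > 0 and sv[1] > 0
        assert np.linalg.matrix_rank(F.F) == 2

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 100, size=(7, 2))
        with pytest.raises(ValueError):
            sl.estimate_fundamental(pts, pts)

    def test_collinear_points_rejected(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t * 100, t * 50])
        with pytest.raises(DegenerateGeometryError):
            sl.estimate_fundamental(pts, pts + 1.0)

    def test_normalization_helps_under_noise(self, small_rig):
        # normalized eight-point should beat the bare version on noisy data
        med = {True: [], False: []}
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            pts = random_scene_points(rng, n=40)
            pi = small_rig[0].project(pts)
            pj = small_rig[1].project(pts)
            pin = pi + rng.normal(0, 0.5, pi.shape)
            pjn = pj + rng.normal(0, 0.5, pj.shape)
            for norm in (True, False):
                F = sl.estimate_fundamental(pin, pjn, normalize=norm)
                # residual evaluated on the clean correspondences
                med[norm].append(np.median(np.abs(F.residuals(pi, pj))))
        assert np.median(med[True]) < np.median(med[False])

    def test_residual_monotone_in_noise(self, small_rig):
        rng = np.random.default_rng(11)
        pts = random_scene_points(rng, n=60)
        pi = small_rig[0].project(pts)
        pj = small_rig[1].project(pts)
        F = sl.estimate_fundamental(pi, pj)
        levels = [0.0, 0.25, 0.5, 1.0]
        means = []
        for sigma in levels:
            vals = []
            for seed in range(8):
                r = np.random.default_rng(200 + seed)
                res = F.residuals(pi + r.normal(0, sigma, pi.shape),
                                  pj + r.normal(0, sigma, pj.shape))
                vals.append(np.abs(res).mean())
            means.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestRectification:
    def test_already_aligned_pair_yields_identity(self):
        cams = make_translation_pair()
        img = np.random.default_rng(0).integers(0, 255, (480, 640)).astype(np.uint8)
        rect = sl.rectify_pair(img, img, cams[0], cams[1])
        for H in rect.homographies:
            Hn = H / H[2, 2]
            np.testing.assert_allclose(Hn, np.eye(3), atol=1e-9)

    def test_converging_pair_aligns_rows(self, small_rig):
        rng = np.random.default_rng(5)
        pts = random_scene_points(rng, n=50)
        img = np.zeros((240, 320), dtype=np.uint8)
        rect = sl.rectify_pair(img, img, small_rig[0], small_rig[1])
        ri = rect.to_rectified(0, small_rig[0].project(pts))
        rj = rect.to_rectified(1, small_rig[1].project(pts))
        assert np.max(np.abs(ri[:, 1] - rj[:, 1])) < 0.5

    def test_homography_roundtrip(self, small_rig):
        img = np.zeros((240, 320), dtype=np.uint8)
        rect = sl.rectify_pair(img, img, small_rig[0], small_rig[1])
        rng = np.random.default_rng(6)
        px = rng.uniform(0, 300, size=(30, 2))
        back = rect.to_original(0, rect.to_rectified(0, px))
        np.testing.assert_allclose(back, px, atol=1e-9)

    def test_uncalibrated_fallback_aligns_rows(self, small_rig):
        rng = np.random.default_rng(7)
        pts = random_scene_points(rng, n=60)
        pi = small_rig[0].project(pts)
        pj = small_rig[1].project(pts)
        img = np.zeros((240, 320), dtype=np.uint8)
        rect = sl.rectify_pair(img, img, correspondences=(pi, pj))
        ri = rect.to_rectified(0, pi)
        rj = rect.to_rectified(1, pj)
        assert np.max(np.abs(ri[:, 1] - rj[:, 1])) < 0.5


class TestPixelRay:
    def test_principal_point_gives_optical_axis(self, small_rig):
        cam = small_rig[0]
        origin, d = sl.pixel_ray(cam, cam.principal_point)
        np.testing.assert_allclose(origin, cam.center, atol=1e-12)
        np.testing.assert_allclose(d, cam.optical_axis, atol=1e-12)

    def test_project_then_cast_roundtrip(self, small_rig):
        cam = small_rig[0]
        rng = np.random.default_rng(8)
        for p in random_scene_points(rng, n=10):
            px = cam.project(p[None, :])[0]
            origin, d = sl.pixel_ray(cam, px)
            v = p - origin
            dist = np.linalg.norm(v - (v @ d) * d)
            assert dist < 1e-9

    def test_unit_norm_directions(self, small_rig):
        rng = np.random.default_rng(9)
        for px in rng.uniform(0, 640, size=(100, 2)):
            _, d = sl.pixel_ray(small_rig[0], px)
            assert abs(np.linalg.norm(d) - 1.0) < 1e-12


class TestCalibrationIO:
    def test_roundtrip(self, tmp_path, small_rig):
        path = tmp_path / "calib.json"
        sl.save_calibration(list(small_rig), path)
        cams = sl.load_calibration(path)
        assert len(cams) == 2
        np.testing.assert_allclose(cams[0].rotation, small_rig[0].rotation)
        np.testing.assert_allclose(cams[0].translation, small_rig[0].translation)
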