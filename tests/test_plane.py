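"""MSAC plane fitting, outlier removal, and Delaunay area estimation."""

import itertools

import numpy as np
import pytest

import skinloc as sl
from skinloc.plane import msac_plane_fit, estimate_area, filter_outliers
from skinloc.triangulation import TriangulatedFeature, TriangulationSet


def exhaustive_msac_oracle(points, threshold):
    """Evaluate every point triple with the truncated-quadratic MSAC cost."""
    pts = np.asarray(points, dtype=float)
    t2 = threshold * threshold
    best_cost, best = np.inf, None
    for (i, j, k) in itertools.combinations(range(len(pts)), 3):
        n = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        offset = n @ pts[i]
        cost = np.minimum((pts @ n - offset) ** 2, t2).sum()
        if cost < best_cost - 1e-15:
            best_cost, best = cost, (n, offset)
    n, offset = best
    inliers = (pts @ n - offset) ** 2 <= t2
    # identical least-squares refit on the inliers
    c = pts[inliers].mean(axis=0)
    _, _, Vt = np.linalg.svd(pts[inliers] - c, full_matrices=False)
    n = Vt[-1]
    offset = float(n @ c)
    inliers = (pts @ n - offset) ** 2 <= t2
    if n[np.argmax(np.abs(n))] < 0:
        n, offset = -n, -offset
    return n, offset, inliers


def planar_cloud_with_outliers(seed, n_in=80, n_out=20, sigma=0.05,
                               slab=20.0):
    rng = np.random.default_rng(seed)
    inl = np.column_stack([rng.uniform(-30, 30, n_in),
                           rng.uniform(-30, 30, n_in),
                           rng.normal(0, sigma, n_in)])
    out = np.column_stack([rng.uniform(-30, 30, n_out),
                           rng.uniform(-30, 30, n_out),
                           rng.uniform(1.0, slab, n_out)
                           * rng.choice([-1, 1], n_out)])
    return np.vstack([inl, out])


def test_exact_plane_recovered():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-10, 10, 50),
                           rng.uniform(-10, 10, 50),
                           np.zeros(50)])
    plane = msac_plane_fit(pts, threshold=0.5, iterations=500, seed=1)
    assert abs(abs(plane.normal[2]) - 1.0) < 1e-9
    assert abs(plane.offset) < 1e-9
    assert plane.inlier_mask.all()
    assert np.max(plane.residuals(pts)) < 1e-9


def test_three_points_fit_exactly():
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0.3], [0.0, 1, -0.2]])
    plane = msac_plane_fit(pts, threshold=1.0, iterations=10, seed=0)
    assert np.max(plane.residuals(pts)) < 1e-9


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        msac_plane_fit(np.zeros((2, 3)), threshold=1.0)
    line = np.outer(np.linspace(0, 1, 10), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="collinear"):
        msac_plane_fit(line, threshold=1.0)


@pytest.mark.parametrize("seed", range(10))
def test_recovery_of_noisy_plane_with_gross_outliers(seed):
    pts = planar_cloud_with_outliers(seed)
    plane = msac_plane_fit(pts, threshold=0.3, iterations=500, seed=seed)
    # at least 78 of the 80 true inliers recovered, normal within 1 degree
    assert plane.inlier_mask[:80].sum() >= 78
    angle = np.degrees(np.arccos(min(abs(plane.normal[2]), 1.0)))
    assert angle < 1.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_equals_exhaustive_triple_oracle_on_small_instances(seed):
    rng = np.random.default_rng(100 + seed)
    pts = planar_cloud_with_outliers(seed, n_in=18, n_out=7)
    sub = pts[rng.permutation(len(pts))[:25]]
    plane = msac_plane_fit(sub, threshold=0.3, iterations=5000, seed=seed)
    n, offset, mask = exhaustive_msac_oracle(sub, 0.3)
    np.testing.assert_allclose(plane.normal, n, atol=1e-9)
    assert plane.offset == pytest.approx(offset, abs=1e-9)
    np.testing.assert_array_equal(plane.inlier_mask, mask)


def test_inlier_count_monotone_in_threshold():
    pts = planar_cloud_with_outliers(3)
    counts = [msac_plane_fit(pts, threshold=th, iterations=800,
                             seed=0).inlier_mask.sum()
              for th in (0.1, 0.3, 1.0, 3.0, 30.0)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_orientation_prior_rejects_misoriented_hypotheses():
    pts = planar_cloud_with_outliers(4, n_out=0, sigma=0.0)
    with pytest.raises(ValueError, match="orientation"):
        # viewing axis along x: every hypothesis is z-normal, outside the cone
        msac_plane_fit(pts, threshold=0.3, iterations=200, seed=0,
                       orientation_axis=[1.0, 0, 0], orientation_max_deg=10.0)
    # with the cone aimed correctly the same cloud fits fine
    plane = msac_plane_fit(pts, threshold=0.3, iterations=200, seed=0,
                           orientation_axis=[0.0, 0, 1.0],
                           orientation_max_deg=10.0)
    assert abs(abs(plane.normal[2]) - 1.0) < 1e-9


def make_tri_set(points, errors=None):
    pts = np.asarray(points, dtype=float)
    errors = np.zeros(len(pts)) if errors is None else errors
    feats = [TriangulatedFeature(pair=(1, 2), index=i + 1, x=p[0], y=p[1],
                                 z=p[2], e=float(errors[i]))
             for i, p in enumerate(pts)]
    return TriangulationSet(pair=(1, 2), features=feats)


class TestFilterOutliers:
    def test_all_inliers_ratio_one(self):
        pts = planar_cloud_with_outliers(0, n_out=0)
        ts = make_tri_set(pts)
        plane = msac_plane_fit(pts, threshold=1.0, iterations=500, seed=0)
        inl, ratio = filter_outliers(ts, plane)
        assert ratio == pytest.approx(1.0)
        assert len(inl) == len(ts)

    def test_ratio_definition(self):
        pts = np.vstack([planar_cloud_with_outliers(1, n_in=10, n_out=0),
                         np.full((30, 3), [0.0, 0.0, 50.0])
                         + np.random.default_rng(0).normal(0, 8, (30, 3))])
        ts = make_tri_set(pts)
        plane = msac_plane_fit(pts, threshold=0.3, iterations=2000, seed=0)
        inl, ratio = filter_outliers(ts, plane, matched_count=40)
        assert ratio == pytest.approx(40 / len(inl))

    def test_known_outlier_mask_matches_truth(self):
        pts = planar_cloud_with_outliers(5)
        ts = make_tri_set(pts)
        plane = msac_plane_fit(pts, threshold=0.3, iterations=500, seed=5)
        inl, ratio = filter_outliers(ts, plane)
        truth = np.abs(pts[:, 2]) <= 0.3
        np.testing.assert_array_equal(plane.inlier_mask, truth)
        assert ratio == pytest.approx(len(pts) / truth.sum())


class TestAreaEstimate:
    def _plane_z0(self, pts):
        return msac_plane_fit(pts, threshold=1.0, iterations=200, seed=0)

    def test_unit_square_cm2(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10, 0], [10.0, 10, 0]])
        est = estimate_area(make_tri_set(pts), self._plane_z0(pts))
        assert est.area_cm2 == pytest.approx(1.00, abs=1e-9)
        assert est.triangle_count == 2

    def test_collinear_points_give_zero_area_with_warning(self):
        pts = np.array([[0.0, 0, 0], [1.0, 1, 0], [2.0, 2, 0], [3.0, 3, 0],
                        [0.0, 5, 0]])
        plane = self._plane_z0(pts)
        line = np.array([[0.0, 0, 0], [1.0, 1, 0], [2.0, 2, 0]])
        with pytest.warns(RuntimeWarning):
            est = estimate_area(make_tri_set(line), plane)
        assert est.area_cm2 == 0.0

    def test_rectangle_with_interior_points(self):
        rng = np.random.default_rng(0)
        corners = np.array([[0.0, 0, 0], [20.0, 0, 0], [0.0, 30, 0],
                            [20.0, 30, 0]])
        interior = np.column_stack([rng.uniform(0, 20, 196),
                                    rng.uniform(0, 30, 196),
                                    np.zeros(196)])
        pts = np.vstack([corners, interior])
        est = estimate_area(make_tri_set(pts), self._plane_z0(pts))
        assert est.area_cm2 == pytest.approx(6.0, rel=0.02)

    def test_delaunay_area_equals_convex_hull_polygon_area(self):
        from scipy.spatial import ConvexHull
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(-15, 15, 60),
                               rng.uniform(-10, 10, 60),
                               np.zeros(60)])
        plane = self._plane_z0(pts)
        est = estimate_area(make_tri_set(pts), plane)
        hull = ConvexHull(pts[:, :2])
        assert est.area_cm2 * 100 == pytest.approx(hull.volume, rel=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-15, 15, 40),
                               rng.uniform(-10, 10, 40),
                               rng.normal(0, 0.02, 40)])
        plane = msac_plane_fit(pts, threshold=0.5, iterations=300, seed=0)
        a0 = estimate_area(make_tri_set(pts), plane).area_cm2
        q = rng.normal(size=(3, 3))
        R = np.linalg.qr(q)[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        t = np.array([5.0, -40.0, 12.0])
        pts2 = pts @ R.T + t
        plane2 = msac_plane_fit(pts2, threshold=0.5, iterations=300, seed=0)
        a1 = estimate_area(make_tri_set(pts2), plane2).area_cm2
        assert a1 == pytest.approx(a0, rel=1e-6)
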