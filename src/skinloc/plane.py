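"""Robust skin-plane fitting, 3-D outlier removal, and area estimation.

The analyzed skin patch is approximated by a single plane.  MSAC (M-estimator
SAmple Consensus) fits the plane to the triangulated cloud: hypotheses are
planes through point triples, scored by the truncated squared residual
``sum(min(r^2, threshold^2))``, and the winner is refit by least squares on
its inliers.  Points farther than the threshold from the plane are discarded
as mismatches.  The analyzed area is the summed Delaunay triangle area of the
inliers' orthogonal projections onto the plane, in cm^2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .triangulation import TriangulationSet

__all__ = ["PlaneModel", "AreaEstimate", "msac_plane_fit", "filter_outliers",
           "estimate_area"]


@dataclass
class PlaneModel:
    """Plane ``n . p = offset`` with unit normal, plus its inlier mask."""

    normal: np.ndarray
    offset: float
    inlier_threshold: float
    inlier_mask: np.ndarray

    def residuals(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs(pts @ self.normal - self.offset)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane axes (deterministic construction)."""
        n = self.normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class AreaEstimate:
    """Summed Delaunay triangle area of projected inliers."""

    area_cm2: float
    triangle_count: int
    boundary_indices: np.ndarray


def _plane_from_triple(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return None
    n = n / norm
    return n, float(n @ p0)


def _lsq_refit(points: np.ndarray):
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    n = Vt[-1]
    return n, float(n @ centroid)


def _canonical_sign(n, offset, axis=None):
    # orient the normal deterministically (toward axis if given)
    ref = axis if axis is not None else None
    if ref is not None and abs(n @ ref) > 1e-12:
        if n @ ref < 0:
            return -n, -offset
        return n, offset
    idx = int(np.argmax(np.abs(n)))
    if n[idx] < 0:
        return -n, -offset
    return n, offset


def msac_plane_fit(points: np.ndarray, threshold: float = 1.0,
                   iterations: int = 1000, seed: int | None = 0,
                   orientation_axis: np.ndarray | None = None,
                   orientation_max_deg: float = 60.0) -> PlaneModel:
    """MSAC plane fit to a 3-D point cloud (mm).

    When the number of point triples does not exceed ``iterations`` every
    triple is evaluated in deterministic order (exhaustive mode); otherwise
    ``iterations`` random triples are drawn from a seeded generator.  An
    optional orientation prior rejects hypotheses whose normal deviates more
    than ``orientation_max_deg`` from ``orientation_axis`` (the rig viewing
    axis, known from the C-arm mechanics).

    The winning hypothesis is refit by total least squares on its inliers
    and the mask recomputed.  Raises on fewer than 3 or collinear points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = len(pts)
    if n_pts < 3:
        raise ValueError("plane fit needs at least 3 points")
    if _lsq_collinear(pts):
        raise ValueError("points are collinear; plane undefined")
    axis = None
    if orientation_axis is not None:
        axis = np.asarray(orientation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    cos_min = np.cos(np.deg2rad(orientation_max_deg))
    t2 = threshold * threshold

    n_triples = n_pts * (n_pts - 1) * (n_pts - 2) // 6
    if n_triples <= iterations:
        triples = itertools.combinations(range(n_pts), 3)
    else:
        rng = np.random.default_rng(seed)
        triples = (sorted(rng.choice(n_pts, size=3, replace=False))
                   for _ in range(iterations))

    best_cost = np.inf
    best_plane = None
    for (i, j, k) in triples:
        hyp = _plane_from_triple(pts[i], pts[j], pts[k])
        if hyp is None:
            continue
        n, offset = hyp
        if axis is not None and abs(n @ axis) < cos_min:
            continue
        r2 = (pts @ n - offset) ** 2
        cost = np.minimum(r2, t2).sum()
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_plane = (n, offset)
    if best_plane is None:
        raise ValueError("no admissible plane hypothesis (orientation prior?)")
    n, offset = best_plane
    inliers = (pts @ n - offset) ** 2 <= t2
    if inliers.sum() >= 3 and not _lsq_collinear(pts[inliers]):
        n, offset = _lsq_refit(pts[inliers])
        inliers = (pts @ n - offset) ** 2 <= t2
    n, offset = _canonical_sign(n, offset, axis)
    return PlaneModel(normal=n, offset=offset, inlier_threshold=threshold,
                      inlier_mask=inliers)


def _lsq_collinear(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[1] < 1e-9 * max(sv[0], 1.0)


def filter_outliers(tri_set: TriangulationSet, plane: PlaneModel,
                    matched_count: int | None = None
                    ) -> tuple[TriangulationSet, float]:
    """Split a triangulation set by the plane's inlier mask.

    Returns the inlier subset and the discard ratio — matched features
    divided by surviving inliers (>= 1 when nothing is spuriously added).
    """
    mask = np.asarray(plane.inlier_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("plane fit left no inliers; check threshold/geometry")
    inliers = tri_set.subset(mask)
    matched = matched_count if matched_count is not None else len(tri_set)
    return inliers, matched / len(inliers)


def estimate_area(inliers: TriangulationSet | np.ndarray,
                  plane: PlaneModel) -> AreaEstimate:
    """Analyzed skin area from the plane-projected inlier cloud (cm^2).

    Points are orthogonally projected onto the plane, triangulated by a 2-D
    Delaunay triangulation in plane coordinates, and the triangle areas
    summed (mm^2 -> cm^2).  Collinear projections yield zero area with a
    warning rather than an error.
    """
    pts = inliers.points() if isinstance(inliers, TriangulationSet) else \
        np.atleast_2d(np.asarray(inliers, dtype=float))
    if len(pts) < 3:
        warnings.warn("fewer than 3 inliers; area undefined, returning 0",
                      RuntimeWarning, stacklevel=2)
        return AreaEstimate(0.0, 0, np.array([], dtype=int))
    u, v = plane.basis()
    proj = pts - np.outer(pts @ plane.normal - plane.offset, plane.normal)
    uv = np.column_stack([proj @ u, proj @ v])
    try:
        tri = Delaunay(uv)
    except QhullError:
        warnings.warn("collinear projected points; area is 0",
                      RuntimeWarning, stacklevel=2)
        return AreaEstimate(0.0, 0, np.array([], dtype=int))
    a = uv[tri.simplices[:, 0]]
    b = uv[tri.simplices[:, 1]]
    c = uv[tri.simplices[:, 2]]
    areas = 0.5 * np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                         - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    boundary = np.unique(tri.convex_hull.ravel())
    return AreaEstimate(area_cm2=float(areas.sum() / 100.0),
                        triangle_count=len(tri.simplices),
                        boundary_indices=boundary)
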