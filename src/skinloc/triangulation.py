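"""Two-view triangulation by the midpoint of the common perpendicular.

For each matched feature, rays are cast from the two camera centers through
the (undistorted, de-rectified) pixels.  In practice the rays never meet
exactly; the shortest segment joining them defines both the 3-D estimate
(the segment's midpoint) and its quality metric ``e`` (the segment's length,
in millimetres) — the *triangulation error* used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel, pixel_ray
from .matching import MatchSet

__all__ = ["TriangulatedFeature", "TriangulationSet", "triangulate",
           "triangulate_matches", "select_pair", "mean_triangulation_error",
           "triangulate_linear"]


class NoVisibilityError(ValueError):
    """No camera pair sees the requested region."""


@dataclass
class TriangulatedFeature:
    """3-D point (mm, rig frame) with its triangulation error."""

    pair: tuple[int, int]
    index: int
    x: float
    y: float
    z: float
    e: float
    degenerate: bool = False
    behind_camera: bool = False

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class TriangulationSet:
    """Triangulated features for one region/acquisition, match-aligned."""

    pair: tuple[int, int]
    features: list[TriangulatedFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i):
        return self.features[i]

    def points(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, 3))
        return np.array([[f.x, f.y, f.z] for f in self.features])

    def errors(self) -> np.ndarray:
        return np.array([f.e for f in self.features])

    def subset(self, mask) -> "TriangulationSet":
        feats = [f for f, m in zip(self.features, mask) if m]
        return TriangulationSet(pair=self.pair, features=feats)


def triangulate(ray_i, ray_j, pair=(0, 0), index=0,
                parallel_eps: float = 1e-8) -> TriangulatedFeature:
    """Midpoint triangulation of two rays ``(origin, unit direction)``.

    Solves for the closest points on each ray; their midpoint is the
    triangulated point and their separation the error ``e``.  Near-parallel
    rays (sine of the inter-ray angle below ``parallel_eps``) raise a
    degenerate-geometry error; a closest point behind either camera flags
    the feature with a cheirality warning instead of failing.
    """
    o1, d1 = (np.asarray(v, dtype=float) for v in ray_i)
    o2, d2 = (np.asarray(v, dtype=float) for v in ray_j)
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < parallel_eps:
        raise ValueError("parallel rays: triangulation degenerate")
    # closest points: o1 + s d1, o2 + t d2 with [d1, -d2] [s t]^T = o2 - o1
    b = o2 - o1
    d12 = d1 @ d2
    denom = 1.0 - d12 * d12
    s = (b @ d1 - (b @ d2) * d12) / denom
    t = ((b @ d1) * d12 - b @ d2) / denom
    p1 = o1 + s * d1
    p2 = o2 + t * d2
    mid = (p1 + p2) / 2.0
    e = float(np.linalg.norm(p1 - p2))
    behind = bool(s < 0 or t < 0)
    if behind:
        warnings.warn("triangulated point behind a camera (cheirality)",
                      RuntimeWarning, stacklevel=2)
    return TriangulatedFeature(pair=pair, index=index,
                               x=float(mid[0]), y=float(mid[1]), z=float(mid[2]),
                               e=e, behind_camera=behind)


def triangulate_matches(match_set: MatchSet, cam_i: CameraModel,
                        cam_j: CameraModel,
                        pixels_i: np.ndarray, pixels_j: np.ndarray
                        ) -> TriangulationSet:
    """Triangulate every match from original-image pixel coordinates.

    ``pixels_i``/``pixels_j`` are (N, 2) arrays aligned with the match set,
    already mapped back from rectified to original image coordinates (the
    rectification homography inverse is applied by the caller/pipeline);
    lens distortion is handled inside ray casting.
    """
    out = TriangulationSet(pair=match_set.pair)
    for n in range(len(match_set)):
        ray_i = pixel_ray(cam_i, pixels_i[n])
        ray_j = pixel_ray(cam_j, pixels_j[n])
        try:
            tf = triangulate(ray_i, ray_j, pair=match_set.pair, index=n + 1)
        except ValueError:
            tf = TriangulatedFeature(pair=match_set.pair, index=n + 1,
                                     x=np.nan, y=np.nan, z=np.nan,
                                     e=np.inf, degenerate=True)
        out.features.append(tf)
    return out


def select_pair(cameras: list[CameraModel], roi_points_3d: np.ndarray,
                image_shape, candidate_pairs=None) -> tuple[int, int]:
    """Pick the camera pair best placed to observe a region.

    A pair qualifies only if every region point projects inside both frames
    (in front of the cameras); among qualifying pairs, the one with the
    widest vergence (baseline) angle at the region centroid wins.  Ties are
    broken by pair order, making the choice deterministic.
    """
    cams = {c.camera_id: c for c in cameras}
    if candidate_pairs is None:
        import itertools
        ids = sorted(cams)
        candidate_pairs = list(itertools.combinations(ids, 2))
    pts = np.atleast_2d(np.asarray(roi_points_3d, dtype=float))
    centroid = pts.mean(axis=0)
    h, w = image_shape
    best, best_angle = None, -1.0
    for (a, b) in candidate_pairs:
        if not (_sees(cams[a], pts, h, w) and _sees(cams[b], pts, h, w)):
            continue
        va = cams[a].center - centroid
        vb = cams[b].center - centroid
        cosang = (va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
        angle = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle > best_angle + 1e-12:
            best, best_angle = (a, b), angle
    if best is None:
        raise NoVisibilityError("no camera pair sees the region")
    return best


def _sees(cam: CameraModel, pts: np.ndarray, h: int, w: int) -> bool:
    camp = pts @ cam.rotation.T + cam.translation
    if np.any(camp[:, 2] <= 0):
        return False
    px = cam.project(pts)
    return bool(np.all((px[:, 0] >= 0) & (px[:, 0] <= w - 1)
                       & (px[:, 1] >= 0) & (px[:, 1] <= h - 1)))


def mean_triangulation_error(tri_set: TriangulationSet | np.ndarray) -> float:
    """Arithmetic mean of the triangulation errors (mm) over all features."""
    errors = tri_set.errors() if isinstance(tri_set, TriangulationSet) else \
        np.asarray(tri_set, dtype=float)
    if errors.size == 0:
        raise ValueError("empty triangulation set")
    return float(errors.mean())


def triangulate_linear(ray_i, ray_j) -> np.ndarray:
    """Linear (SVD) two-ray triangulation, provided as a cross-check only."""
    o1, d1 = (np.asarray(v, float) for v in ray_i)
    o2, d2 = (np.asarray(v, float) for v in ray_j)
    rows = []
    rhs = []
    for o, d in ((o1, d1), (o2, d2)):
        d = d / np.linalg.norm(d)
        P = np.eye(3) - np.outer(d, d)  # distance-to-line projector
        rows.append(P)
        rhs.append(P @ o)
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol
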