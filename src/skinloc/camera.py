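"""Pinhole camera model and multi-view geometry for a small convergent rig.

All world/rig coordinates are in millimetres.  Pixel coordinates are 0-based
with ``x`` the column (rightward) and ``y`` the row (downward), origin at the
center of the top-left pixel.

The rig mirrors the intraoperative setup this package targets: up to four
grey-scale cameras rigidly mounted on a flat detector, converging on the
patient's skin.  Six ordered camera pairs are admissible for a 4-camera rig.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "FundamentalMatrix",
    "RectifiedPair",
    "camera_pairs",
    "correct_intrinsics",
    "distort_normalized",
    "undistort_points",
    "estimate_fundamental",
    "rectify_pair",
    "pixel_ray",
    "load_calibration",
    "save_calibration",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric estimation problem is degenerate."""


@dataclass
class CameraModel:
    """Calibrated pinhole camera with polynomial lens distortion.

    Parameters
    ----------
    camera_id : int
        Identifier in ``{1..4}`` (rig position).
    focal : (float, float)
        Focal lengths ``(fx, fy)`` in pixels.
    principal_point : (float, float)
        ``(cx, cy)`` in pixels.
    distortion : sequence of 5 floats
        ``[k1, k2, p1, p2, k3]`` — radial (k) and tangential (p) coefficients.
    rotation : (3, 3) array
        World-to-camera rotation (orthonormal, det +1).
    translation : (3,) array
        World-to-camera translation in millimetres: ``x_cam = R x_world + t``.
    """

    camera_id: int
    focal: tuple[float, float]
    principal_point: tuple[float, float]
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.distortion.size < 5:
            self.distortion = np.pad(self.distortion, (0, 5 - self.distortion.size))
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        fx, fy = self.focal
        if not (fx > 0 and fy > 0):
            raise ValueError("focal lengths must be positive")
        RtR = self.rotation.T @ self.rotation
        if not np.allclose(RtR, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix (zero skew)."""
        fx, fy = self.focal
        cx, cy = self.principal_point
        return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm): ``C = -R^T t``."""
        return -self.rotation.T @ self.translation

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit viewing direction in world coordinates (third row of R)."""
        return self.rotation[2]

    def project(self, points: np.ndarray, distort: bool = True) -> np.ndarray:
        """Project (N, 3) world points (mm) to (N, 2) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = pts @ self.rotation.T + self.translation
        xn = cam[:, 0] / cam[:, 2]
        yn = cam[:, 1] / cam[:, 2]
        if distort and np.any(self.distortion):
            xn, yn = distort_normalized(xn, yn, self.distortion)
        fx, fy = self.focal
        cx, cy = self.principal_point
        out = np.column_stack([fx * xn + cx, fy * yn + cy])
        return out if np.asarray(points).ndim == 2 else out[0]


def camera_pairs(cameras: list[CameraModel]) -> list[tuple[int, int]]:
    """All ordered camera-id pairs ``(ci, cj)`` with ``ci < cj``.

    A 4-camera rig yields exactly six pairs.
    """
    ids = sorted(c.camera_id for c in cameras)
    return list(itertools.combinations(ids, 2))


# ---------------------------------------------------------------------------
# Lens distortion
# ---------------------------------------------------------------------------

def distort_normalized(xn, yn, dist):
    """Apply the radial/tangential polynomial to normalized coordinates."""
    k1, k2, p1, p2, k3 = np.asarray(dist, dtype=float)[:5]
    r2 = xn * xn + yn * yn
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = xn * radial + 2.0 * p1 * xn * yn + p2 * (r2 + 2.0 * xn * xn)
    yd = yn * radial + p1 * (r2 + 2.0 * yn * yn) + 2.0 * p2 * xn * yn
    return xd, yd


def undistort_points(pixels: np.ndarray, camera: CameraModel,
                     iterations: int = 10, tol: float = 1e-8) -> np.ndarray:
    """Invert the distortion polynomial for pixel coordinates.

    Fixed-point iteration (at most ``iterations`` passes, stopping early once
    the update is below ``tol`` pixels in normalized units scaled by focal).
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    xd = (px[:, 0] - cx) / fx
    yd = (px[:, 1] - cy) / fy
    if not np.any(camera.distortion):
        out = np.column_stack([px[:, 0], px[:, 1]])
        return out if np.asarray(pixels).ndim == 2 else out[0]
    k1, k2, p1, p2, k3 = camera.distortion[:5]
    x, y = xd.copy(), yd.copy()
    for _ in range(iterations):
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        x_new = (xd - dx) / radial
        y_new = (yd - dy) / radial
        step = max(np.max(np.abs(x_new - x)) * fx, np.max(np.abs(y_new - y)) * fy)
        x, y = x_new, y_new
        if step < tol:
            break
    out = np.column_stack([fx * x + cx, fy * y + cy])
    return out if np.asarray(pixels).ndim == 2 else out[0]


def correct_intrinsics(image: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Undistort an 8-bit grayscale image onto the same pixel grid.

    Each output pixel samples the input at its forward-distorted location
    (bilinear interpolation).  With all distortion coefficients zero the input
    is returned unchanged.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.any(camera.distortion):
        return img.copy()
    h, w = img.shape
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xn = (u - cx) / fx
    yn = (v - cy) / fy
    xd, yd = distort_normalized(xn, yn, camera.distortion)
    src_x = fx * xd + cx
    src_y = fy * yd + cy
    out = _bilinear_sample(img.astype(float), src_x, src_y)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def _bilinear_sample(img: np.ndarray, x: np.ndarray, y: np.ndarray,
                     fill: float = 0.0) -> np.ndarray:
    """Bilinearly sample float image at (x, y); out-of-bounds -> fill."""
    h, w = img.shape
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    valid = (x >= 0) & (y >= 0) & (x <= w - 1) & (y <= h - 1)
    x0c = np.clip(x0, 0, w - 2)
    y0c = np.clip(y0, 0, h - 2)
    dx = np.clip(x, 0, w - 1) - x0c
    dy = np.clip(y, 0, h - 1) - y0c
    i00 = img[y0c, x0c]
    i01 = img[y0c, x0c + 1]
    i10 = img[y0c + 1, x0c]
    i11 = img[y0c + 1, x0c + 1]
    out = (i00 * (1 - dx) * (1 - dy) + i01 * dx * (1 - dy)
           + i10 * (1 - dx) * dy + i11 * dx * dy)
    return np.where(valid, out, fill)


# ---------------------------------------------------------------------------
# Fundamental matrix
# ---------------------------------------------------------------------------

@dataclass
class FundamentalMatrix:
    """Rank-2 fundamental matrix satisfying ``x'^T F x = 0``.

    Normalized to unit Frobenius norm with the largest-magnitude entry
    positive (deterministic sign).
    """

    F: np.ndarray

    def residuals(self, points_i: np.ndarray, points_j: np.ndarray) -> np.ndarray:
        """Algebraic epipolar residuals ``x'^T F x`` per correspondence."""
        xi = _homog(points_i)
        xj = _homog(points_j)
        return np.einsum("ni,ij,nj->n", xj, self.F, xi)

    @property
    def epipoles(self) -> tuple[np.ndarray, np.ndarray]:
        """(e, e') with ``F e = 0`` and ``F^T e' = 0`` (homogeneous)."""
        _, _, Vt = np.linalg.svd(self.F)
        e = Vt[-1]
        _, _, Vt2 = np.linalg.svd(self.F.T)
        ep = Vt2[-1]
        return e, ep


def _homog(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.column_stack([pts, np.ones(len(pts))])


def _normalizing_transform(points: np.ndarray) -> np.ndarray:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    if d < 1e-12:
        raise DegenerateGeometryError("coincident points")
    s = np.sqrt(2.0) / d
    return np.array([[s, 0, -s * centroid[0]],
                     [0, s, -s * centroid[1]],
                     [0, 0, 1.0]])


def estimate_fundamental(points_i: np.ndarray, points_j: np.ndarray,
                         normalize: bool = True) -> FundamentalMatrix:
    """Normalized eight-point estimate of F from >= 8 correspondences.

    The rank-2 constraint is enforced by zeroing the smallest singular value.
    ``normalize=False`` runs the bare (unnormalized) eight-point algorithm,
    exposed for accuracy comparisons.
    """
    pi = np.atleast_2d(np.asarray(points_i, dtype=float))
    pj = np.atleast_2d(np.asarray(points_j, dtype=float))
    if len(pi) != len(pj):
        raise ValueError("point lists must have equal length")
    if len(pi) < 8:
        raise ValueError("at least 8 correspondences required")
    _check_not_collinear(pi)
    _check_not_collinear(pj)
    if normalize:
        Ti = _normalizing_transform(pi)
        Tj = _normalizing_transform(pj)
    else:
        Ti = Tj = np.eye(3)
    hi = _homog(pi) @ Ti.T
    hj = _homog(pj) @ Tj.T
    # x'^T F x = 0 rows: kron(x', x)
    A = np.einsum("ni,nj->nij", hj, hi).reshape(len(pi), 9)
    _, s, Vt = np.linalg.svd(A)
    F = Vt[-1].reshape(3, 3)
    U, sv, Vt2 = np.linalg.svd(F)
    sv = sv.copy()
    sv[2] = 0.0
    F = U @ np.diag(sv) @ Vt2
    F = Tj.T @ F @ Ti
    F = F / np.linalg.norm(F)
    idx = np.unravel_index(np.argmax(np.abs(F)), F.shape)
    if F[idx] < 0:
        F = -F
    return FundamentalMatrix(F=F)


def _check_not_collinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are (near-)collinear")


# ---------------------------------------------------------------------------
# Rectification
# ---------------------------------------------------------------------------

@dataclass
class RectifiedPair:
    """A row-aligned stereo pair with the pixel->rectified homographies."""

    images: tuple[np.ndarray, np.ndarray]
    homographies: tuple[np.ndarray, np.ndarray]
    pair: tuple[int, int]

    def to_rectified(self, side: int, pixels: np.ndarray) -> np.ndarray:
        return _apply_h(self.homographies[side], pixels)

    def to_original(self, side: int, pixels: np.ndarray) -> np.ndarray:
        return _apply_h(np.linalg.inv(self.homographies[side]), pixels)


def _apply_h(H: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    hp = _homog(pixels) @ H.T
    out = hp[:, :2] / hp[:, 2:3]
    return out if np.asarray(pixels).ndim == 2 else out[0]


def rectification_homographies(cam_i: CameraModel, cam_j: CameraModel
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated epipolar rectification (common rotation, shared row axis).

    The new camera frame has its x-axis along the baseline and z-axis close
    to the mean optical axis; both views share the averaged intrinsics, so
    corresponding points land on identical rows.
    """
    Ci, Cj = cam_i.center, cam_j.center
    baseline = Cj - Ci
    nb = np.linalg.norm(baseline)
    if nb < 1e-9:
        raise DegenerateGeometryError("coincident camera centers")
    v1 = baseline / nb
    z_mean = cam_i.optical_axis + cam_j.optical_axis
    v2 = np.cross(z_mean, v1)
    n2 = np.linalg.norm(v2)
    if n2 < 1e-9:
        raise DegenerateGeometryError("baseline parallel to viewing axis")
    v2 = v2 / n2
    v3 = np.cross(v1, v2)
    R_new = np.vstack([v1, v2, v3])
    if np.linalg.det(R_new) < 0:  # keep right-handed
        R_new = np.vstack([v1, -v2, -v3])
    K_new = (cam_i.K + cam_j.K) / 2.0
    K_new[0, 1] = 0.0
    Hi = K_new @ R_new @ cam_i.rotation.T @ np.linalg.inv(cam_i.K)
    Hj = K_new @ R_new @ cam_j.rotation.T @ np.linalg.inv(cam_j.K)
    return Hi, Hj


def _epipole_inside(cam_a: CameraModel, cam_b: CameraModel, shape) -> bool:
    """True if camera b's center projects inside camera a's image."""
    c = cam_a.rotation @ cam_b.center + cam_a.translation
    if abs(c[2]) < 1e-12:
        return False
    px = cam_a.project(cam_b.center[None, :], distort=False)[0]
    h, w = shape
    return c[2] > 0 and 0 <= px[0] <= w - 1 and 0 <= px[1] <= h - 1


def rectify_pair(image_i: np.ndarray, image_j: np.ndarray,
                 cam_i: CameraModel | None = None,
                 cam_j: CameraModel | None = None,
                 F: FundamentalMatrix | None = None,
                 correspondences: tuple[np.ndarray, np.ndarray] | None = None,
                 interpolation: str = "bilinear") -> RectifiedPair:
    """Resample an image pair so corresponding points share a row.

    Uses calibrated rectification when both camera models are given;
    otherwise falls back to the uncalibrated (F-based) method, which needs
    ``F`` (or correspondences to estimate it from) plus the correspondences
    for the shearing/matching transform.
    """
    if cam_i is not None and cam_j is not None:
        if _epipole_inside(cam_i, cam_j, image_i.shape) or \
           _epipole_inside(cam_j, cam_i, image_j.shape):
            raise DegenerateGeometryError("epipole inside image; cannot rectify")
        Hi, Hj = rectification_homographies(cam_i, cam_j)
        pair = (cam_i.camera_id, cam_j.camera_id)
    else:
        if F is None:
            if correspondences is None:
                raise ValueError("need cameras, F, or correspondences")
            F = estimate_fundamental(*correspondences)
        if correspondences is None:
            raise ValueError("uncalibrated rectification needs correspondences")
        Hi, Hj = _uncalibrated_homographies(F, correspondences, image_j.shape)
        pair = (0, 0)
    Hi, Hj = _recenter_homographies(Hi, Hj, image_i.shape, image_j.shape)
    warped_i = warp_homography(image_i, Hi, image_i.shape, interpolation)
    warped_j = warp_homography(image_j, Hj, image_j.shape, interpolation)
    return RectifiedPair(images=(warped_i, warped_j),
                         homographies=(Hi, Hj), pair=pair)


def _recenter_homographies(Hi, Hj, shape_i, shape_j):
    """Shift both homographies (shared y, per-image x) to keep frames on-grid."""
    def center_map(H, shape):
        h, w = shape
        c = _apply_h(H, np.array([[(w - 1) / 2.0, (h - 1) / 2.0]]))[0]
        return c

    ci = center_map(Hi, shape_i)
    cj = center_map(Hj, shape_j)
    hy = (shape_i[0] - 1) / 2.0
    ty = hy - (ci[1] + cj[1]) / 2.0  # common vertical shift keeps rows aligned
    Ti = np.array([[1, 0, (shape_i[1] - 1) / 2.0 - ci[0]], [0, 1, ty], [0, 0, 1.0]])
    Tj = np.array([[1, 0, (shape_j[1] - 1) / 2.0 - cj[0]], [0, 1, ty], [0, 0, 1.0]])
    return Ti @ Hi, Tj @ Hj


def warp_homography(image: np.ndarray, H: np.ndarray, out_shape,
                    interpolation: str = "bilinear") -> np.ndarray:
    """Warp image by pixel->rectified homography H (inverse sampling)."""
    h, w = out_shape
    Hinv = np.linalg.inv(H)
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = _homog(np.column_stack([u.ravel(), v.ravel()])) @ Hinv.T
    sx = (src[:, 0] / src[:, 2]).reshape(h, w)
    sy = (src[:, 1] / src[:, 2]).reshape(h, w)
    if interpolation == "nearest":
        xi = np.rint(sx).astype(int)
        yi = np.rint(sy).astype(int)
        valid = (xi >= 0) & (yi >= 0) & (xi < image.shape[1]) & (yi < image.shape[0])
        out = np.zeros(out_shape, dtype=float)
        out[valid] = image.astype(float)[yi[valid], xi[valid]]
    else:
        out = _bilinear_sample(np.asarray(image, dtype=float), sx, sy)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(np.asarray(image).dtype)
    return out


def _uncalibrated_homographies(F: FundamentalMatrix, correspondences, shape_j):
    """Hartley-style rectification from F: send e' to infinity, then match."""
    pts_i, pts_j = (np.atleast_2d(np.asarray(p, float)) for p in correspondences)
    h, w = shape_j
    e, ep = F.epipoles
    if abs(ep[2]) > 1e-12 and 0 <= ep[0] / ep[2] <= w - 1 and 0 <= ep[1] / ep[2] <= h - 1:
        raise DegenerateGeometryError("epipole inside image; cannot rectify")
    # translate image-j center to origin
    T = np.array([[1, 0, -(w - 1) / 2.0], [0, 1, -(h - 1) / 2.0], [0, 0, 1.0]])
    ept = T @ ep
    if abs(ept[2]) > 1e-12:
        ept = ept / ept[2]
    norm = np.hypot(ept[0], ept[1])
    ca, sa = ept[0] / norm, ept[1] / norm
    Rrot = np.array([[ca, sa, 0], [-sa, ca, 0], [0, 0, 1.0]])
    er = Rrot @ ept
    G = np.eye(3)
    if abs(er[2]) > 1e-12:
        G[2, 0] = -er[2] / er[0]
    Hj = np.linalg.inv(T) @ G @ Rrot @ T
    # matching homography for image i: Hi = Ha Hj M, M from F = [e']_x M
    ex = np.array([[0, -ep[2], ep[1]], [ep[2], 0, -ep[0]], [-ep[1], ep[0], 0]])
    M = ex @ F.F + np.outer(ep, np.ones(3))
    H0 = Hj @ M
    a = _apply_h(H0, pts_i)
    b = _apply_h(Hj, pts_j)
    A = np.column_stack([a, np.ones(len(a))])
    coef, *_ = np.linalg.lstsq(A, b[:, 0], rcond=None)
    Ha = np.array([[coef[0], coef[1], coef[2]], [0, 1, 0], [0, 0, 1.0]])
    return Ha @ H0, Hj


# ---------------------------------------------------------------------------
# Rays
# ---------------------------------------------------------------------------

def pixel_ray(camera: CameraModel, pixel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cast the viewing ray through a (sub-)pixel.

    Returns ``(origin, direction)`` with the origin at the camera center (mm)
    and a unit direction in world coordinates.  The pixel is undistorted
    first when the camera has distortion.
    """
    px = np.asarray(pixel, dtype=float).reshape(2)
    if not np.all(np.isfinite(px)):
        raise ValueError("pixel must be finite")
    if np.any(camera.distortion):
        px = undistort_points(px[None, :], camera)[0] if px.ndim == 1 else px
        px = np.asarray(px).reshape(2)
    fx, fy = camera.focal
    cx, cy = camera.principal_point
    d_cam = np.array([(px[0] - cx) / fx, (px[1] - cy) / fy, 1.0])
    d_world = camera.rotation.T @ d_cam
    d_world = d_world / np.linalg.norm(d_world)
    return camera.center, d_world


# ---------------------------------------------------------------------------
# Calibration I/O
# ---------------------------------------------------------------------------

def save_calibration(cameras: list[CameraModel], path) -> None:
    """Write the rig calibration as the standard JSON (units mm)."""
    records = []
    for c in cameras:
        records.append({
            "camera_id": int(c.camera_id),
            "fx": float(c.focal[0]), "fy": float(c.focal[1]),
            "cx": float(c.principal_point[0]), "cy": float(c.principal_point[1]),
            "dist": [float(v) for v in c.distortion[:5]],
            "R": [float(v) for v in c.rotation.ravel()],
            "t": [float(v) for v in c.translation],
            "units": "mm",
        })
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_calibration(path) -> list[CameraModel]:
    """Read a rig calibration JSON written by :func:`save_calibration`."""
    with open(path) as fh:
        records = json.load(fh)
    cams = []
    for r in records:
        cams.append(CameraModel(
            camera_id=r["camera_id"],
            focal=(r["fx"], r["fy"]),
            principal_point=(r["cx"], r["cy"]),
            distortion=np.array(r["dist"], dtype=float),
            rotation=np.array(r["R"], dtype=float).reshape(3, 3),
            translation=np.array(r["t"], dtype=float),
        ))
    return cams
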