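"""Ground-truthed synthetic multi-camera scenes for the localization pipeline.

Emulates what the clinical rig sees: a near-planar patch of skin carrying
dark elliptical blobs (moles, pigment spots) and bright circular optical
markers, imaged by four convergent cameras mounted on a flat detector about
600 mm above the skin.  Every scene is fully deterministic given its seed
and exports exact 3-D feature/marker positions plus their per-camera
projections, so the pipeline's output can be scored against truth.

Geometry is metric (mm).  Rendering rasterizes each analytic ellipse through
the exact per-blob plane-to-image homography with supersampled coverage, so
projected centroids are faithful to well below a tenth of a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel, camera_pairs, undistort_points

__all__ = ["SceneConfig", "GroundTruth", "make_rig", "render"]


@dataclass
class SceneConfig:
    """Scene and rig description; all lengths in mm, intensities 8-bit.

    The defaults define the package's reference study conditions: a
    60 x 45 mm skin patch at ~10 px/mm with 25 blobs of 1-2.5 mm radius,
    four corner markers, and 0.2 mm out-of-plane blob jitter.
    """

    seed: int
    image_size: tuple[int, int] = (640, 480)     # (width, height) px
    focal: float = 6000.0                        # px
    camera_distance: float = 600.0               # mm above the patch
    camera_spread: float = 160.0                 # detector square side, mm
    n_cameras: int = 4
    distortion: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    plane_extent: tuple[float, float] = (44.0, 33.0)   # mm
    plane_tilt_deg: float = 3.0                  # patch tilt about x-axis
    n_blobs: int = 20
    blob_radius_range: tuple[float, float] = (1.0, 2.5)   # mm
    blob_intensity_range: tuple[int, int] = (60, 120)
    blob_elongation_max: float = 1.8
    n_markers: int = 4
    marker_radius: float = 3.0                   # mm
    marker_intensity: int = 250
    background: int = 180
    noise_sigma: float = 0.0                     # px: per-camera image jitter
    intensity_noise: float = 0.0                 # grey levels: additive noise
    illumination_gradient: float = 0.0           # intensity span across image
    tilt_sigma: float = 0.2                      # out-of-plane blob jitter, mm
    supersample: int = 8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_blobs < 0 or self.n_markers < 0:
            raise ValueError("counts must be >= 0")

    @classmethod
    def compact(cls, seed: int, **overrides) -> "SceneConfig":
        """Small scene for fast sweeps (320 x 240, ~5 px/mm, 12 blobs)."""
        kw = dict(image_size=(320, 240), focal=3000.0,
                  plane_extent=(50.0, 36.0), n_blobs=12, n_markers=4,
                  blob_radius_range=(1.2, 2.5), marker_radius=3.0)
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def uhd(cls, seed: int, **overrides) -> "SceneConfig":
        """Clinical-resolution preset (2592 x 1920 lines)."""
        kw = dict(image_size=(2592, 1920), focal=24000.0,
                  plane_extent=(60.0, 45.0))
        kw.update(overrides)
        return cls(seed=seed, **kw)


@dataclass
class GroundTruth:
    """Exact 3-D scene content and its per-camera projections."""

    blob_centers: np.ndarray          # (B, 3) mm
    blob_radii: np.ndarray            # (B,) mm, semi-major
    marker_centers: np.ndarray        # (M, 3) mm
    plane_normal: np.ndarray
    plane_offset: float
    blob_projections: dict[int, np.ndarray] = field(default_factory=dict)
    marker_projections: dict[int, np.ndarray] = field(default_factory=dict)


def _look_at(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation with +z toward the target, +y downward-ish."""
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, -1.0, 0.0])  # image y grows downward
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def make_rig(config: SceneConfig) -> list[CameraModel]:
    """Build the convergent rig: cameras on a square, aimed at the origin.

    All pairwise vergence angles exceed 5 degrees for the default geometry;
    a narrower layout raises.
    """
    if config.n_cameras < 2:
        raise ValueError("rig needs at least 2 cameras")
    w, h = config.image_size
    half = config.camera_spread / 2.0
    corners = [(-half, -half), (half, -half), (-half, half), (half, half),
               (0.0, -half), (0.0, half), (-half, 0.0), (half, 0.0)]
    target = np.zeros(3)
    cams = []
    for i in range(config.n_cameras):
        cx, cy = corners[i % len(corners)]
        C = np.array([cx, cy, config.camera_distance])
        R = _look_at(C, target)
        t = -R @ C
        cams.append(CameraModel(
            camera_id=i + 1, focal=(config.focal, config.focal),
            principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
            distortion=np.array(config.distortion), rotation=R, translation=t))
    axes = np.array([c.optical_axis for c in cams])
    for a, b in camera_pairs(cams):
        cosang = axes[a - 1] @ axes[b - 1]
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 5.0:
            raise ValueError("rig vergence below 5 degrees; widen the spread")
    return cams


def _plane_frame(config: SceneConfig):
    """Base-plane origin and in-plane unit axes (tilted about x)."""
    a = np.deg2rad(config.plane_tilt_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, np.cos(a), np.sin(a)])
    normal = np.cross(e1, e2)
    return np.zeros(3), e1, e2, normal


def _sample_scene(config: SceneConfig, rng: np.random.Generator):
    origin, e1, e2, normal = _plane_frame(config)
    ex, ey = config.plane_extent
    rmin, rmax = config.blob_radius_range

    blob_uv = []
    radii = []
    tries = 0
    while len(blob_uv) < config.n_blobs and tries < 20000:
        tries += 1
        r = rng.uniform(rmin, rmax)
        u = rng.uniform(-ex / 2 + 2 * rmax, ex / 2 - 2 * rmax)
        v = rng.uniform(-ey / 2 + 2 * rmax, ey / 2 - 2 * rmax)
        if all((u - pu) ** 2 + (v - pv) ** 2 > (2.2 * rmax) ** 2
               for pu, pv in blob_uv):
            blob_uv.append((u, v))
            radii.append(r)
    blob_uv = np.array(blob_uv) if blob_uv else np.zeros((0, 2))
    radii = np.array(radii)
    elong = rng.uniform(1.0, config.blob_elongation_max, size=len(radii))
    angles = rng.uniform(0, np.pi, size=len(radii))
    intensities = rng.uniform(*config.blob_intensity_range, size=len(radii))
    jitter = rng.normal(0.0, config.tilt_sigma, size=len(radii))

    mx = ex / 2 - 1.5 * config.marker_radius
    my = ey / 2 - 1.5 * config.marker_radius
    marker_uv = np.array([(-mx, -my), (mx, -my), (-mx, my), (mx, my),
                          (0.0, -my), (0.0, my)])[:config.n_markers]

    blob_centers = (origin + blob_uv @ np.vstack([e1, e2])
                    + jitter[:, None] * normal) if len(radii) else np.zeros((0, 3))
    marker_centers = (origin + marker_uv @ np.vstack([e1, e2])
                      if config.n_markers else np.zeros((0, 3)))
    return {
        "e1": e1, "e2": e2, "normal": normal,
        "blob_centers": blob_centers, "blob_radii": radii,
        "blob_elong": elong, "blob_angles": angles,
        "blob_intensities": intensities,
        "marker_centers": marker_centers,
    }


def _ellipse_homography(cam: CameraModel, center, a1, a2):
    """3x3 map from ellipse-plane (alpha, beta, 1) to homogeneous pixels."""
    K, R, t = cam.K, cam.rotation, cam.translation
    return np.column_stack([K @ R @ a1, K @ R @ a2, K @ (R @ center + t)])


def _render_ellipse(img: np.ndarray, cam: CameraModel, center, a1, a2,
                    intensity: float, ss: int) -> None:
    """Alpha-composite one unit-disc ellipse patch into the image."""
    H = _ellipse_homography(cam, center, a1, a2)
    th = np.linspace(0, 2 * np.pi, 33)
    boundary = np.column_stack([np.cos(th), np.sin(th), np.ones_like(th)]) @ H.T
    bpx = boundary[:, :2] / boundary[:, 2:3]
    h, w = img.shape
    x0 = max(int(np.floor(bpx[:, 0].min())) - 2, 0)
    x1 = min(int(np.ceil(bpx[:, 0].max())) + 3, w)
    y0 = max(int(np.floor(bpx[:, 1].min())) - 2, 0)
    y1 = min(int(np.ceil(bpx[:, 1].max())) + 3, h)
    if x1 <= x0 or y1 <= y0:
        return
    Hinv = np.linalg.inv(H)
    off = (np.arange(ss) + 0.5) / ss - 0.5
    us = (np.arange(x0, x1)[:, None] + off[None, :]).ravel()
    vs = (np.arange(y0, y1)[:, None] + off[None, :]).ravel()
    U, V = np.meshgrid(us, vs)
    P = np.stack([U, V, np.ones_like(U)], axis=-1) @ Hinv.T
    alpha = P[..., 0] / P[..., 2]
    beta = P[..., 1] / P[..., 2]
    inside = (alpha ** 2 + beta ** 2) <= 1.0
    cov = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    block = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = block * (1 - cov) + intensity * cov


def render(config: SceneConfig, cameras: list[CameraModel] | None = None
           ) -> tuple[dict[int, np.ndarray], GroundTruth]:
    """Render the scene through every camera; returns images and truth.

    Images are uint8 grayscale keyed by camera id.  ``noise_sigma`` (px)
    models unmodelled acquisition jitter: each camera's rendered content is
    displaced by an independent Gaussian sub-pixel offset, so feature
    projections deviate from the calibrated geometry by that order —
    ground-truth projections record the *exact* geometry.  ``intensity_noise``
    (grey levels) adds per-pixel Gaussian noise.  All randomness comes from
    seeded streams, so the same seed always yields bit-identical images.
    """
    rng = np.random.default_rng(config.seed)
    cams = cameras if cameras is not None else make_rig(config)
    scene = _sample_scene(config, rng)
    w, h = config.image_size
    e1, e2 = scene["e1"], scene["e2"]
    images: dict[int, np.ndarray] = {}
    noise_root = np.random.default_rng(config.seed + 1)
    for cam in cams:
        img = np.full((h, w), float(config.background))
        if config.illumination_gradient:
            img += config.illumination_gradient * \
                (np.arange(w)[None, :] / max(w - 1, 1) - 0.5)
        jitter = noise_root.normal(0.0, 1.0, size=2) * config.noise_sigma
        cam_r = cam if not np.any(jitter) else _jittered(cam, jitter)
        for b in range(len(scene["blob_radii"])):
            r = scene["blob_radii"][b]
            elong = scene["blob_elong"][b]
            ang = scene["blob_angles"][b]
            u = np.cos(ang) * e1 + np.sin(ang) * e2
            v = -np.sin(ang) * e1 + np.cos(ang) * e2
            _render_ellipse(img, cam_r, scene["blob_centers"][b],
                            r * u, (r / elong) * v,
                            scene["blob_intensities"][b], config.supersample)
        for m in range(len(scene["marker_centers"])):
            _render_ellipse(img, cam_r, scene["marker_centers"][m],
                            config.marker_radius * e1, config.marker_radius * e2,
                            float(config.marker_intensity), config.supersample)
        if np.any(np.asarray(config.distortion)):
            img = _apply_distortion(img, cam)
        if config.intensity_noise > 0:
            img = img + noise_root.normal(0.0, config.intensity_noise,
                                          size=img.shape)
        images[cam.camera_id] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        blob_centers=scene["blob_centers"], blob_radii=scene["blob_radii"],
        marker_centers=scene["marker_centers"],
        plane_normal=scene["normal"],
        plane_offset=float(scene["normal"] @ np.zeros(3)),
    )
    for cam in cams:
        if len(gt.blob_centers):
            gt.blob_projections[cam.camera_id] = cam.project(gt.blob_centers)
        else:
            gt.blob_projections[cam.camera_id] = np.zeros((0, 2))
        if len(gt.marker_centers):
            gt.marker_projections[cam.camera_id] = cam.project(gt.marker_centers)
        else:
            gt.marker_projections[cam.camera_id] = np.zeros((0, 2))
    return images, gt


def _jittered(cam: CameraModel, delta_px: np.ndarray) -> CameraModel:
    """Rendering-only camera copy whose image content is shifted by delta."""
    import dataclasses
    cx, cy = cam.principal_point
    return dataclasses.replace(
        cam, principal_point=(cx + float(delta_px[0]), cy + float(delta_px[1])))


def _apply_distortion(img: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Resample an ideal (undistorted) rendering into distorted pixels."""
    from .camera import _bilinear_sample
    h, w = img.shape
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    px = np.column_stack([u.ravel(), v.ravel()])
    src = undistort_points(px, cam)
    return _bilinear_sample(img, src[:, 0].reshape(h, w), src[:, 1].reshape(h, w),
                            fill=float(img.mean()))
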