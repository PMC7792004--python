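"""End-to-end markerless localization pipeline and its run report.

Stages: intrinsic correction -> CLAHE -> pair selection -> epipolar
rectification -> blob detection (MSER and/or fast-Hessian) inside ROIs ->
upright descriptor extraction -> scan-line SSD matching -> sub-pixel
refinement in original image geometry -> midpoint triangulation -> MSAC
plane outlier removal -> area and descriptive statistics.

Detection and matching run on the rectified pair (rows aligned); matched
feature centers are mapped back through the rectification homographies and
refined by an iterated intensity-weighted centroid in the undistorted
original image before ray casting, so triangulation is not degraded by the
rectification resampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .camera import CameraModel, correct_intrinsics, rectify_pair
from .clahe import ClaheParams, clahe
from .fast_hessian import FastHessianParams, detect_fast_hessian, extract_descriptors
from .features import FeatureEnsemble, Roi
from .markers import compare_to_ground_truth, detect_markers, segment_markers
from .matching import MatchParams, match_scanline_ssd
from .mser import MserParams, detect_mser
from .plane import estimate_area, filter_outliers, msac_plane_fit
from .simulate import GroundTruth, SceneConfig, make_rig, render
from .stats import aggregate_regions, compute_region_stats
from .triangulation import (TriangulationSet, mean_triangulation_error,
                            select_pair, triangulate_matches)

__all__ = ["PipelineConfig", "run_localization", "run_on_scene",
           "refine_centroid", "benchmark_markers"]


@dataclass
class PipelineConfig:
    """Every stage's tunables, mirrored in the YAML config."""

    detector: str = "both"                    # mser | surf | both
    clahe_enabled: bool = True
    clahe: ClaheParams = field(default_factory=ClaheParams)
    mser: MserParams = field(default_factory=lambda: MserParams(polarity="dark"))
    fast_hessian: FastHessianParams = field(default_factory=FastHessianParams)
    match: MatchParams = field(default_factory=MatchParams)
    msac_threshold_mm: float = 1.0
    msac_iterations: int = 1000
    msac_orientation_max_deg: float = 60.0
    refine_radius_scale: float = 2.5
    refine_iterations: int = 3
    seed: int = 0

    def detectors(self) -> list[str]:
        if self.detector not in ("mser", "surf", "both"):
            raise ValueError("detector must be mser|surf|both")
        return ["MSER", "SURF"] if self.detector == "both" else \
            [self.detector.upper()]


def refine_centroid(image: np.ndarray, x: float, y: float, radius: float,
                    iterations: int = 3) -> tuple[float, float]:
    """Blob-adaptive intensity-weighted centroid around (x, y).

    Within a window of the given radius, the local background is the median
    of the window border and the blob polarity the sign of the central
    contrast.  The blob support is the connected component of the
    half-contrast threshold containing the strongest pixel near the seed;
    the centroid is weighted by background contrast over that component
    dilated by a few pixels (capturing the anti-aliased skirt, which carries
    the sub-pixel information).  The window grows (up to ``iterations``
    times) if the component touches its border, so the result does not
    depend on the detector's scale estimate.  Returns the input location
    when no contrast is found.
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = max(int(np.ceil(radius)), 4)
    cx, cy = float(x), float(y)
    for attempt in range(max(iterations, 1)):
        x0, x1 = max(int(round(cx)) - r, 0), min(int(round(cx)) + r + 1, w)
        y0, y1 = max(int(round(cy)) - r, 0), min(int(round(cy)) + r + 1, h)
        win = img[y0:y1, x0:x1]
        if win.shape[0] < 5 or win.shape[1] < 5:
            return cx, cy
        border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        bg = np.median(border)
        # polarity from the strongest contrast near the seed
        sy, sx = int(round(cy)) - y0, int(round(cx)) - x0
        sy = np.clip(sy, 2, win.shape[0] - 3)
        sx = np.clip(sx, 2, win.shape[1] - 3)
        patch = win[sy - 2:sy + 3, sx - 2:sx + 3]
        contrast = float(bg - patch.mean())
        diff = (bg - win) if contrast >= 0 else (win - bg)
        peak = diff.max()
        if peak <= 1e-9:
            return cx, cy
        support = diff >= peak / 2.0
        labels, n = ndimage.label(support)
        if n == 0:
            return cx, cy
        # component holding the strongest supported pixel nearest the seed
        yy, xx = np.nonzero(support)
        d2 = (xx - (cx - x0)) ** 2 + (yy - (cy - y0)) ** 2
        comp = labels[yy[d2.argmin()], xx[d2.argmin()]]
        mask = labels == comp
        touches = (mask[0].any() or mask[-1].any()
                   or mask[:, 0].any() or mask[:, -1].any())
        if touches and attempt < iterations - 1:
            r = int(r * 1.6) + 2
            continue
        skirt = ndimage.binary_dilation(mask, iterations=3)
        wgt = np.where(skirt, np.maximum(diff, 0.0), 0.0)
        total = wgt.sum()
        if total <= 0:
            return cx, cy
        gy, gx = np.mgrid[y0:y1, x0:x1]
        return float((wgt * gx).sum() / total), float((wgt * gy).sum() / total)
    return cx, cy


def _detect(image: np.ndarray, roi: Roi, detector: str, cfg: PipelineConfig
            ) -> FeatureEnsemble:
    if detector == "MSER":
        return detect_mser(image, roi, cfg.mser)
    return detect_fast_hessian(image, roi, cfg.fast_hessian)


def _map_roi(roi: Roi, H: np.ndarray, shape) -> Roi:
    """Bounding box of a ROI warped by a homography, clipped to the frame."""
    from .camera import _apply_h
    corners = np.array([[roi.x, roi.y], [roi.x + roi.width, roi.y],
                        [roi.x, roi.y + roi.height],
                        [roi.x + roi.width, roi.y + roi.height]], dtype=float)
    warped = _apply_h(H, corners)
    x0 = int(np.floor(warped[:, 0].min()))
    y0 = int(np.floor(warped[:, 1].min()))
    x1 = int(np.ceil(warped[:, 0].max()))
    y1 = int(np.ceil(warped[:, 1].max()))
    return Roi(roi.camera_id, x0, y0, max(x1 - x0, 1), max(y1 - y0, 1)).clip_to(shape)


def run_localization(images: dict[int, np.ndarray],
                     cameras: list[CameraModel],
                     rois: list[Roi],
                     config: PipelineConfig | None = None,
                     pair: tuple[int, int] | None = None,
                     workspace_points: np.ndarray | None = None) -> dict:
    """Localize skin features in 3-D for each region of interest.

    ``rois`` lists one region per entry (coordinates in the first camera of
    the chosen pair; regions are re-used across the pair via the rectified
    frame).  The camera pair is chosen by visibility/vergence when
    ``workspace_points`` (rough 3-D extent of the skin patch, mm) are given,
    else it must be passed explicitly.

    Returns the run report: per-detector per-region statistics, pooled TOT
    row, intermediate counts, and the fitted plane per region.
    """
    config = config or PipelineConfig()
    cams = {c.camera_id: c for c in cameras}
    sample = next(iter(images.values()))
    if pair is None:
        if workspace_points is None:
            raise ValueError("need an explicit pair or workspace_points")
        pair = select_pair(cameras, workspace_points, sample.shape)
    ci, cj = pair

    undistorted = {cid: correct_intrinsics(images[cid], cams[cid])
                   for cid in (ci, cj)}
    ideal_cams = {cid: dataclasses.replace(cams[cid], distortion=np.zeros(5))
                  for cid in (ci, cj)}
    enhanced = {cid: clahe(undistorted[cid], config.clahe)
                if config.clahe_enabled else undistorted[cid]
                for cid in (ci, cj)}
    rect = rectify_pair(enhanced[ci], enhanced[cj],
                        ideal_cams[ci], ideal_cams[cj])
    Hi, Hj = rect.homographies

    report: dict = {
        "version": __version__,
        "pair": [ci, cj],
        "seed": config.seed,
        "config": {"detector": config.detector,
                   "msac_threshold_mm": config.msac_threshold_mm,
                   "clahe_enabled": config.clahe_enabled,
                   "band": config.match.band},
        "detectors": {},
    }
    view_axis = -(cams[ci].optical_axis + cams[cj].optical_axis)
    view_axis /= np.linalg.norm(view_axis)

    for det in config.detectors():
        regions = []
        clouds = []
        for ridx, roi in enumerate(rois):
            res = _localize_region(rect, undistorted, ideal_cams, roi, det,
                                   config, view_axis, region_id=f"R{ridx + 1}")
            regions.append(res)
            if res.get("inlier_points") is not None:
                clouds.append(res)
        ok = [r for r in regions if "stats" in r]
        block = {"regions": [r["stats"] for r in ok],
                 "failures": [r for r in regions if "stats" not in r],
                 "clouds": clouds}
        if ok:
            block["total"] = aggregate_regions(
                [r["errors"] for r in ok],
                [r["stats"]["area_cm2"] for r in ok],
                [r["matched"] for r in ok]).as_dict()
        report["detectors"][det] = block
    return report


def _localize_region(rect, undistorted, ideal_cams, roi, detector,
                     config: PipelineConfig, view_axis, region_id) -> dict:
    ci, cj = rect.pair
    Hi, Hj = rect.homographies
    img_ri, img_rj = rect.images
    try:
        roi_i = _map_roi(roi, Hi, img_ri.shape)
        roi_j = _map_roi(dataclasses.replace(roi, camera_id=cj), Hj, img_rj.shape)
    except ValueError:
        return {"region_id": region_id, "reason": "roi outside frame"}
    ens_i = _detect(img_ri, roi_i, detector, config)
    ens_j = _detect(img_rj, roi_j, detector, config)
    ens_i, d_i = extract_descriptors(img_ri, ens_i)
    ens_j, d_j = extract_descriptors(img_rj, ens_j)
    if not len(ens_i) or not len(ens_j):
        return {"region_id": region_id, "reason": "no features detected",
                "n_i": len(ens_i), "n_j": len(ens_j)}
    ms = match_scanline_ssd(d_i, d_j, config.match,
                            x_i=ens_i.locations()[:, 0],
                            x_j=ens_j.locations()[:, 0])
    if not len(ms):
        return {"region_id": region_id, "reason": "no matches",
                "n_i": len(ens_i), "n_j": len(ens_j)}
    px_i = _refined_pixels(rect, 0, undistorted[ci], ens_i, ms.indices_i, config)
    px_j = _refined_pixels(rect, 1, undistorted[cj], ens_j, ms.indices_j, config)
    tri = triangulate_matches(ms, ideal_cams[ci], ideal_cams[cj], px_i, px_j)
    good = np.array([not (f.degenerate or f.behind_camera) for f in tri])
    tri = tri.subset(good)
    if len(tri) < 3:
        return {"region_id": region_id, "reason": "too few triangulations",
                "matched": len(ms)}
    try:
        plane = msac_plane_fit(tri.points(), threshold=config.msac_threshold_mm,
                               iterations=config.msac_iterations,
                               seed=config.seed,
                               orientation_axis=view_axis,
                               orientation_max_deg=config.msac_orientation_max_deg)
        inliers, discard = filter_outliers(tri, plane, matched_count=len(ms))
    except ValueError as exc:
        return {"region_id": region_id, "reason": str(exc), "matched": len(ms)}
    area = estimate_area(inliers, plane)
    if area.area_cm2 <= 0:
        return {"region_id": region_id, "reason": "degenerate area",
                "matched": len(ms)}
    stats = compute_region_stats(inliers.errors(), area.area_cm2,
                                 matched_count=len(ms), region_id=region_id)
    return {
        "region_id": region_id,
        "stats": stats.as_dict(),
        "errors": inliers.errors(),
        "matched": len(ms),
        "n_i": len(ens_i), "n_j": len(ens_j),
        "plane_normal": plane.normal, "plane_offset": plane.offset,
        "inlier_points": inliers.points(),
        "outlier_points": tri.points()[~plane.inlier_mask],
        "mean_error_mm": mean_triangulation_error(inliers),
    }


def _refined_pixels(rect, side: int, raw_image, ensemble, indices, config):
    """Rectified feature centers -> refined original-image pixels."""
    locs = ensemble.locations()[list(indices)]
    orig = rect.to_original(side, locs)
    out = np.empty_like(orig)
    for k, (i, (ox, oy)) in enumerate(zip(indices, orig)):
        scale = ensemble[i].scale
        rx, ry = refine_centroid(raw_image, ox, oy,
                                 radius=max(config.refine_radius_scale * scale, 10.0),
                                 iterations=config.refine_iterations)
        out[k] = (rx, ry)
    return out


# ---------------------------------------------------------------------------
# Marker benchmark
# ---------------------------------------------------------------------------

def benchmark_markers(images: dict[int, np.ndarray],
                      cameras: list[CameraModel],
                      gt_markers: np.ndarray,
                      pair: tuple[int, int],
                      method: str = "MSER",
                      intensity_threshold: float | None = None,
                      band: float = 2.0,
                      max_assign_dist: float = 2.0,
                      refine: bool = True) -> dict:
    """Detect, match, triangulate and benchmark the bright optical markers.

    Marker detections in the two views are matched on rectified rows (row
    clusters sorted by column — valid for coplanar markers), triangulated by
    the same midpoint code path as the skin features, and assigned to the
    ground-truth coordinates by greedy nearest neighbour.
    """
    cams = {c.camera_id: c for c in cameras}
    ci, cj = pair
    und = {cid: correct_intrinsics(images[cid], cams[cid]) for cid in (ci, cj)}
    ideal = {cid: dataclasses.replace(cams[cid], distortion=np.zeros(5))
             for cid in (ci, cj)}
    rect = rectify_pair(und[ci], und[cj], ideal[ci], ideal[cj])

    dets = {}
    for s, cid in enumerate(pair):
        mask = segment_markers(und[cid], intensity_threshold)
        found = detect_markers(und[cid], mask, method=method, camera_id=cid)
        centers = np.array([[d.x, d.y] for d in found]) if found else np.zeros((0, 2))
        if refine and len(found):
            centers = np.array([
                refine_centroid(und[cid], d.x, d.y, radius=2.0 * d.radius)
                for d in found])
        rows = rect.to_rectified(s, centers)[:, 1] if len(found) else np.array([])
        cols = rect.to_rectified(s, centers)[:, 0] if len(found) else np.array([])
        dets[cid] = {"centers": centers, "rows": rows, "cols": cols}

    pairs_idx = _match_rows(dets[ci], dets[cj], band)
    if not pairs_idx:
        raise ValueError("no marker matches between the two views")
    from .matching import MatchSet
    ms = MatchSet(pair=pair, indices_i=[a for a, _ in pairs_idx],
                  indices_j=[b for _, b in pairs_idx],
                  ssd=[0.0] * len(pairs_idx))
    px_i = dets[ci]["centers"][ms.indices_i]
    px_j = dets[cj]["centers"][ms.indices_j]
    tri = triangulate_matches(ms, ideal[ci], ideal[cj], px_i, px_j)
    pts = tri.points()
    comps, unassigned = compare_to_ground_truth(
        pts, gt_markers, max_assign_dist=max_assign_dist,
        triangulation_errors=tri.errors())
    dists = np.array([c.euclidean_distance for c in comps])
    terrs = np.array([c.triangulation_error for c in comps])
    from .stats import describe
    return {
        "method": method,
        "n_detected": int(len(pts)),
        "n_matched_to_gt": int(len(comps)),
        "unassigned_gt": unassigned,
        "mean_euclidean_mm": float(dists.mean()) if len(comps) else np.nan,
        "mean_triangulation_error_mm": float(terrs.mean()) if len(comps) else np.nan,
        "euclidean_stats": describe(dists) if len(comps) else None,
        "triangulation_stats": describe(terrs) if len(comps) else None,
        "comparisons": comps,
        "triangulated": pts,
    }


def _match_rows(det_i: dict, det_j: dict, band: float) -> list[tuple[int, int]]:
    """Row-cluster matching of marker detections (column order within rows)."""
    ri, rj = det_i["rows"], det_j["rows"]
    pairs: list[tuple[int, int]] = []
    used_j: set[int] = set()
    for i in np.argsort(ri, kind="stable"):
        cand = [j for j in np.argsort(rj, kind="stable")
                if j not in used_j and abs(ri[i] - rj[j]) <= band]
        if not cand:
            continue
        # among same-row candidates keep column ordering: nearest column wins
        j = min(cand, key=lambda j: (abs(det_j["cols"][j] - det_i["cols"][i]),
                                     abs(ri[i] - rj[j])))
        used_j.add(j)
        pairs.append((int(i), int(j)))
    return pairs


# ---------------------------------------------------------------------------
# Synthetic-scene convenience
# ---------------------------------------------------------------------------

def run_on_scene(scene: SceneConfig, config: PipelineConfig | None = None,
                 roi_margin: int = 8) -> dict:
    """Render a synthetic scene and run the full pipeline on it.

    The ROI is the full frame minus a margin; the camera pair is selected
    from the patch's 3-D corner points.  The report gains a ``truth`` block
    scoring localization against the scene's exact blob positions.
    """
    config = config or PipelineConfig(seed=scene.seed)
    cams = make_rig(scene)
    images, gt = render(scene, cams)
    w, h = scene.image_size
    roi = Roi(1, roi_margin, roi_margin, w - 2 * roi_margin, h - 2 * roi_margin)
    ex, ey = scene.plane_extent
    corners = np.array([[sx * ex / 2, sy * ey / 2, 0.0]
                        for sx in (-1, 1) for sy in (-1, 1)])
    report = run_localization(images, cams, [roi], config,
                              workspace_points=corners)
    report["truth"] = {}
    for det, block in report["detectors"].items():
        scored = _score_against_truth(block, gt)
        report["truth"][det] = scored
    report["scene"] = {"seed": scene.seed, "noise_sigma": scene.noise_sigma,
                       "n_blobs": scene.n_blobs}
    report["images"] = images
    report["ground_truth"] = gt
    return report


def _score_against_truth(block: dict, gt: GroundTruth, tol_mm: float = 0.5,
                         strict_tol_mm: float = 0.05) -> dict:
    clouds = block.get("clouds", [])
    if not clouds or not len(gt.blob_centers):
        return {"recovered_fraction": 0.0, "n_recovered": 0,
                "strict_fraction": 0.0, "mean_3d_error_mm": float("nan")}
    pts = np.vstack([c["inlier_points"] for c in clouds])
    errs = np.concatenate([c["errors"] for c in clouds])
    d = np.linalg.norm(gt.blob_centers[:, None, :] - pts[None, :, :], axis=2)
    nearest = d.min(axis=1)
    recovered = nearest <= tol_mm
    # per blob: smallest triangulation error among features localized within
    # the strict 3-D tolerance (inf when none is that close)
    best_e = np.full(len(gt.blob_centers), np.inf)
    for b in range(len(gt.blob_centers)):
        close = d[b] <= strict_tol_mm
        if close.any():
            best_e[b] = errs[close].min()
    return {
        "recovered_fraction": float(recovered.mean()),
        "n_recovered": int(recovered.sum()),
        "n_blobs": int(len(gt.blob_centers)),
        "mean_3d_error_mm": float(nearest[recovered].mean())
        if recovered.any() else float("nan"),
        "max_3d_error_mm": float(nearest[recovered].max())
        if recovered.any() else float("nan"),
        "nearest_errors_mm": nearest,
        "best_e_within_strict_mm": best_e,
        "strict_fraction": float(((nearest <= strict_tol_mm)
                                  & (best_e < 1e-3)).mean()),
    }
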