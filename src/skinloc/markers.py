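"""Optical-marker detection and ground-truth benchmarking.

The clinical rig tracks adhesive optical markers whose 3-D positions are
known from the navigation system; they serve as ground truth for the
markerless skin-feature localization.  Markers appear as bright circular
regions, so detection is: binarize, drop small components, then run the
chosen blob detector (MSER or fast-Hessian) inside each component and keep
its strongest response.  Localization accuracy is the per-marker 3-D
Euclidean distance between detected and ground-truth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .fast_hessian import FastHessianParams, detect_fast_hessian
from .features import Roi
from .mser import MserParams, detect_mser

__all__ = ["MarkerDetection", "MarkerComparison", "segment_markers",
           "detect_markers", "compare_to_ground_truth"]


@dataclass
class MarkerDetection:
    """One detected marker in one camera image (sub-pixel center)."""

    camera_id: int
    x: float
    y: float
    radius: float
    method: str


@dataclass
class MarkerComparison:
    """Detected vs ground-truth 3-D marker positions (mm)."""

    marker_id: int
    detected: np.ndarray
    ground_truth: np.ndarray
    euclidean_distance: float
    triangulation_error: float = np.nan


def segment_markers(image: np.ndarray, intensity_threshold: float | None = None,
                    min_area: int = 5) -> np.ndarray:
    """Binary marker mask: pixels >= threshold, small components removed.

    With ``intensity_threshold=None`` Otsu's threshold on the image histogram
    is used (the manual override reproduces simple fixed binarization).
    """
    img = np.asarray(image)
    if intensity_threshold is None:
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=bool)
        intensity_threshold = threshold_otsu(img)
        # skin images are three-class (dark blobs / skin / bright markers);
        # when the first split leaves an implausibly large bright class,
        # re-threshold within it to isolate the markers
        frac = float((img >= intensity_threshold).mean())
        upper = img[img >= intensity_threshold]
        if frac > 0.05 and upper.min() != upper.max():
            intensity_threshold = threshold_otsu(upper)
    mask = img >= intensity_threshold
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n:
        areas = np.bincount(labels.ravel())
        small = np.nonzero(areas < min_area)[0]
        mask[np.isin(labels, small[small > 0])] = False
    return mask


def detect_markers(image: np.ndarray, mask: np.ndarray, method: str = "MSER",
                   camera_id: int = 0) -> list[MarkerDetection]:
    """One sub-pixel detection per connected marker component.

    The detector runs on the masked image (background zeroed); within each
    component the highest-response feature wins.  If the detector finds
    nothing inside a component (e.g. a tiny or saturated disc), the
    intensity-weighted centroid of the component is used instead.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    masked = np.where(mask, img, 0.0).astype(np.uint8)
    labels, n = ndimage.label(mask)
    detections: list[MarkerDetection] = []
    for comp in range(1, n + 1):
        ys, xs = np.nonzero(labels == comp)
        pad = max(int(0.5 * (np.ptp(ys) + np.ptp(xs))), 8)
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, img.shape[0])
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, img.shape[1])
        roi = Roi(camera_id, int(x0), int(y0), int(x1 - x0), int(y1 - y0))
        if method.upper() == "MSER":
            ens = detect_mser(masked, roi, MserParams(
                polarity="bright", min_area=3,
                max_area=max(int(1.5 * len(ys)), 10)))
        else:
            ens = detect_fast_hessian(masked, roi, FastHessianParams(
                hessian_threshold=10.0))
        radius = float(np.sqrt(len(ys) / np.pi))
        wsum = img[ys, xs].sum()
        wx = float((img[ys, xs] * xs).sum() / wsum)
        wy = float((img[ys, xs] * ys).sum() / wsum)
        # candidate features must sit near the component centroid: large
        # discs excite strong rim responses that are not marker centers
        inside = [f for f in ens
                  if 0 <= int(round(f.y)) < img.shape[0]
                  and 0 <= int(round(f.x)) < img.shape[1]
                  and labels[int(round(f.y)), int(round(f.x))] == comp
                  and np.hypot(f.x - wx, f.y - wy) <= 0.5 * radius]
        if inside:
            best = max(inside, key=lambda f: (f.response, -f.index))
            cx, cy = best.x, best.y
        else:
            cx, cy = wx, wy  # intensity-weighted centroid fallback
        detections.append(MarkerDetection(camera_id=camera_id, x=cx, y=cy,
                                          radius=radius, method=method.upper()))
    return detections


def compare_to_ground_truth(detected_3d: np.ndarray, gt_3d: np.ndarray,
                            max_assign_dist: float = 2.0,
                            triangulation_errors: np.ndarray | None = None
                            ) -> tuple[list[MarkerComparison], list[int]]:
    """Greedy one-to-one assignment of detections to ground-truth markers.

    Candidate pairings are sorted by ascending Euclidean distance and
    accepted while both endpoints are unassigned and the distance does not
    exceed ``max_assign_dist`` (mm).  Returns the comparisons plus the list
    of unassigned ground-truth marker ids.
    """
    det = np.atleast_2d(np.asarray(detected_3d, dtype=float))
    gt = np.atleast_2d(np.asarray(gt_3d, dtype=float))
    if det.size == 0 or gt.size == 0:
        raise ValueError("both marker lists must be nonempty")
    d = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"),
                                       d.shape))[0]
    used_det: set[int] = set()
    used_gt: set[int] = set()
    comparisons: list[MarkerComparison] = []
    for i, j in order:
        if d[i, j] > max_assign_dist:
            break
        if i in used_det or j in used_gt:
            continue
        used_det.add(int(i))
        used_gt.add(int(j))
        te = float(triangulation_errors[i]) if triangulation_errors is not None \
            else np.nan
        comparisons.append(MarkerComparison(
            marker_id=int(j), detected=det[i], ground_truth=gt[j],
            euclidean_distance=float(d[i, j]), triangulation_error=te))
    comparisons.sort(key=lambda c: c.marker_id)
    unassigned = [j for j in range(len(gt)) if j not in used_gt]
    return comparisons, unassigned
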