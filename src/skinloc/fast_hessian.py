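"""Fast-Hessian blob detection and upright SURF-style descriptors.

Blob detection follows the box-filter approximation of the scale-normalized
Hessian determinant on an integral image; descriptors are 64-dimensional
Haar-wavelet response summaries over a 4x4 spatial grid.  Descriptors are
computed *upright* (no orientation assignment): the pipeline matches on
rectified image pairs whose rows are aligned, so rotation invariance is
unnecessary and omitting it improves distinctiveness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Descriptor, DescriptorSet, Feature, FeatureEnsemble, Roi

__all__ = ["FastHessianParams", "integral_image", "box_sum",
           "hessian_response", "detect_fast_hessian", "extract_descriptors"]


@dataclass
class FastHessianParams:
    """Fast-Hessian configuration.

    hessian_threshold : minimum determinant response for a keypoint.
    n_octaves, n_scales : octave/scale grid (filter sizes grow with both).
    """

    hessian_threshold: float = 20.0
    n_octaves: int = 3
    n_scales: int = 4


def integral_image(image: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero top/left border row/column."""
    img = np.asarray(image, dtype=np.float64)
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    ii[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    return ii


def box_sum(ii: np.ndarray, r0, c0, r1, c1):
    """Sum of pixels in rows [r0, r1] x cols [c0, c1] inclusive (arrays ok)."""
    return ii[r1 + 1, c1 + 1] - ii[r0, c1 + 1] - ii[r1 + 1, c0] + ii[r0, c0]


def _filter_sizes(n_octaves: int, n_scales: int) -> list[int]:
    """SURF filter-size ladder: 9,15,21,27; 15,27,39,51; 27,51,75,99..."""
    sizes: list[int] = []
    for o in range(n_octaves):
        step = 6 * (2 ** o)
        base = 9 + (0 if o == 0 else (3 * (2 ** o) - 3) * 2)
        for k in range(n_scales):
            s = base + k * step
            if s not in sizes:
                sizes.append(s)
    return sorted(sizes)


def hessian_response(ii: np.ndarray, size: int) -> np.ndarray:
    """Scale-normalized box-filter det(Hessian) for one filter size.

    ``size`` must be ``9 + 6k``; responses where the filter exceeds the image
    are set to 0.  Uses the conventional 0.9 weight on the mixed term.
    """
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    lobe = size // 3
    half = size // 2
    resp = np.zeros((h, w))
    rows = np.arange(h)
    cols = np.arange(w)
    r0 = half
    r1 = h - half - 1
    if r1 < r0 or (w - half - 1) < half:
        return resp
    R, C = np.meshgrid(rows[r0:r1 + 1], cols[half:w - half], indexing="ij")

    # Dyy: 3 vertically stacked lobe-row boxes, (2*lobe-1) columns wide;
    # lobe is odd (size = 3*lobe, size = 9+6k), so boxes center exactly.
    cw = lobe - 1  # half-width of the (2*lobe-1)-wide box
    lh = (lobe - 1) // 2
    whole = box_sum(ii, R - half, C - cw, R + half, C + cw)
    mid = box_sum(ii, R - lh, C - cw, R + lh, C + cw)
    dyy = whole - 3.0 * mid

    whole_x = box_sum(ii, R - cw, C - half, R + cw, C + half)
    mid_x = box_sum(ii, R - cw, C - lh, R + cw, C + lh)
    dxx = whole_x - 3.0 * mid_x

    q = lobe  # quadrant box side for Dxy
    dxy = (box_sum(ii, R - q, C + 1, R - 1, C + q)
           + box_sum(ii, R + 1, C - q, R + q, C - 1)
           - box_sum(ii, R - q, C - q, R - 1, C - 1)
           - box_sum(ii, R + 1, C + 1, R + q, C + q))

    # per-term normalization 1/(9*size): equals 1/size^2 at the base size 9
    # and scales so a Gaussian blob of width sigma peaks near the filter with
    # equivalent sigma = 1.2*size/9 (LoG-like scale selection)
    norm = 1.0 / (9.0 * size)
    dxx *= norm
    dyy *= norm
    dxy *= norm
    det = dxx * dyy - (0.9 * dxy) ** 2
    resp[r0:r1 + 1, half:w - half] = det
    return resp


def detect_fast_hessian(image: np.ndarray, roi: Roi | None = None,
                        params: FastHessianParams | None = None
                        ) -> FeatureEnsemble:
    """Detect blobs as 3x3x3 scale-space maxima of the fast-Hessian response.

    Keypoints are refined to sub-pixel/sub-scale position by fitting a
    quadratic to the response neighbourhood.  ``scale`` is the SURF
    convention ``1.2 * size / 9``.
    """
    params = params or FastHessianParams()
    img = np.asarray(image, dtype=np.float64)
    cam_id = roi.camera_id if roi is not None else 0
    if roi is None:
        roi = Roi(cam_id, 0, 0, img.shape[1], img.shape[0])
    roi = roi.clip_to(img.shape)
    sub = img[roi.y:roi.y + roi.height, roi.x:roi.x + roi.width]
    sizes = _filter_sizes(params.n_octaves, params.n_scales)
    sizes = [s for s in sizes if s <= min(sub.shape)]
    if len(sizes) < 3:
        return FeatureEnsemble(camera_id=cam_id)
    ii = integral_image(sub)
    stack = np.stack([hessian_response(ii, s) for s in sizes])
    feats = []
    th = params.hessian_threshold
    S, H, W = stack.shape
    for si in range(1, S - 1):
        layer = stack[si]
        cand = layer > th
        if not np.any(cand):
            continue
        ys, xs = np.nonzero(cand)
        keep = (ys >= 1) & (ys < H - 1) & (xs >= 1) & (xs < W - 1)
        for y, x in zip(ys[keep], xs[keep]):
            v = layer[y, x]
            cube = stack[si - 1:si + 2, y - 1:y + 2, x - 1:x + 2]
            if v < cube.max() or (cube == v).sum() > 1 and not _is_first_max(cube, v):
                continue
            ds, dy, dx = _quadratic_offset(cube)
            if max(abs(ds), abs(dy), abs(dx)) > 1.0:
                ds = dy = dx = 0.0
            size = sizes[si] + ds * (sizes[si + 1] - sizes[si - 1]) / 2.0
            feats.append(Feature(
                camera_id=cam_id, index=0,
                x=float(roi.x + x + dx), y=float(roi.y + y + dy),
                scale=float(1.2 * size / 9.0), detector="SURF",
                response=float(v), polarity=0))
    return FeatureEnsemble(camera_id=cam_id, features=feats).reindex()


def _is_first_max(cube: np.ndarray, v: float) -> bool:
    """Deterministic tie-break: keep only the first maximal entry (center)."""
    flat = cube.ravel()
    return int(np.argmax(flat == v)) == 13  # center of the 3x3x3 cube


def _quadratic_offset(cube: np.ndarray) -> tuple[float, float, float]:
    """Sub-sample offset of the extremum from central finite differences."""
    d = np.array([
        (cube[2, 1, 1] - cube[0, 1, 1]) / 2.0,
        (cube[1, 2, 1] - cube[1, 0, 1]) / 2.0,
        (cube[1, 1, 2] - cube[1, 1, 0]) / 2.0,
    ])
    Hm = np.empty((3, 3))
    c = cube[1, 1, 1]
    Hm[0, 0] = cube[2, 1, 1] - 2 * c + cube[0, 1, 1]
    Hm[1, 1] = cube[1, 2, 1] - 2 * c + cube[1, 0, 1]
    Hm[2, 2] = cube[1, 1, 2] - 2 * c + cube[1, 1, 0]
    Hm[0, 1] = Hm[1, 0] = (cube[2, 2, 1] - cube[2, 0, 1]
                           - cube[0, 2, 1] + cube[0, 0, 1]) / 4.0
    Hm[0, 2] = Hm[2, 0] = (cube[2, 1, 2] - cube[2, 1, 0]
                           - cube[0, 1, 2] + cube[0, 1, 0]) / 4.0
    Hm[1, 2] = Hm[2, 1] = (cube[1, 2, 2] - cube[1, 2, 0]
                           - cube[1, 0, 2] + cube[1, 0, 0]) / 4.0
    try:
        off = -np.linalg.solve(Hm, d)
    except np.linalg.LinAlgError:
        return 0.0, 0.0, 0.0
    return float(off[0]), float(off[1]), float(off[2])


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _haar_responses(ii: np.ndarray, px: np.ndarray, py: np.ndarray, s: int):
    """Haar dx/dy responses of side 2s at integer sample points."""
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    valid = (px - s >= 0) & (py - s >= 0) & (px + s - 1 <= w - 1) & (py + s - 1 <= h - 1)
    pxc = np.clip(px, s, max(w - s, s))
    pyc = np.clip(py, s, max(h - s, s))
    right = box_sum(ii, pyc - s, pxc, pyc + s - 1, pxc + s - 1)
    left = box_sum(ii, pyc - s, pxc - s, pyc + s - 1, pxc - 1)
    down = box_sum(ii, pyc, pxc - s, pyc + s - 1, pxc + s - 1)
    up = box_sum(ii, pyc - s, pxc - s, pyc - 1, pxc + s - 1)
    dx = np.where(valid, right - left, 0.0)
    dy = np.where(valid, down - up, 0.0)
    return dx, dy, valid


def descriptor_at(image_ii: np.ndarray, x: float, y: float, scale: float,
                  scale_cap: float = 6.0) -> np.ndarray | None:
    """64-d upright descriptor at (x, y); None if the window leaves the image.

    The 20s x 20s window is sampled on a 20x20 grid with spacing ``s`` (s
    rounded to >= 1 integer for the Haar boxes), split into 4x4 subregions of
    5x5 samples; each subregion contributes (sum dx, sum |dx|, sum dy,
    sum |dy|), Gaussian-weighted (sigma = 3.3 s) and normalized to unit length.

    ``scale_cap`` bounds the sampling scale so very large blobs keep a
    practical window (matching works on rectified pairs where corresponding
    features have near-identical scales, so capping both sides is benign).
    """
    s = max(int(round(min(scale, scale_cap))), 1)
    h, w = image_ii.shape[0] - 1, image_ii.shape[1] - 1
    grid = np.arange(-10, 10) + 0.5
    gx, gy = np.meshgrid(grid, grid)
    px = np.rint(x + gx * s).astype(int)
    py = np.rint(y + gy * s).astype(int)
    if px.min() - s < 0 or py.min() - s < 0 or px.max() + s > w or py.max() + s > h:
        return None
    dx, dy, valid = _haar_responses(image_ii, px, py, s)
    if not valid.all():
        return None
    g = np.exp(-(gx ** 2 + gy ** 2) / (2 * 3.3 ** 2))
    dx = dx * g
    dy = dy * g
    vec = np.empty(64)
    k = 0
    for by in range(4):
        for bx in range(4):
            sl = (slice(by * 5, by * 5 + 5), slice(bx * 5, bx * 5 + 5))
            vec[k:k + 4] = (dx[sl].sum(), np.abs(dx[sl]).sum(),
                            dy[sl].sum(), np.abs(dy[sl]).sum())
            k += 4
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return np.zeros(64)  # constant patch: flagged unmatchable downstream
    return vec / norm


def extract_descriptors(image: np.ndarray, ensemble: FeatureEnsemble,
                        scale_cap: float = 6.0
                        ) -> tuple[FeatureEnsemble, DescriptorSet]:
    """Describe every feature; drop border features from both containers.

    Returns the (possibly reduced) ensemble and the aligned descriptor set.
    The descriptor's ``y_row`` is the feature's row coordinate in the image
    the descriptors are computed on (the rectified image in the pipeline).
    """
    img = np.asarray(image, dtype=np.float64)
    ii = integral_image(img)
    kept: list[Feature] = []
    descs: list[Descriptor] = []
    for f in ensemble:
        vec = descriptor_at(ii, f.x, f.y, f.scale, scale_cap=scale_cap)
        if vec is None:
            continue
        kept.append(f)
        descs.append(Descriptor(vector=vec, y_row=f.y))
    out = FeatureEnsemble(camera_id=ensemble.camera_id, features=kept)
    for n, f in enumerate(out.features, start=1):
        f.index = n
    return out, DescriptorSet(camera_id=ensemble.camera_id, descriptors=descs)
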