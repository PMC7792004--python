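"""Maximally Stable Extremal Regions via an incremental component tree.

Detects blob-like skin features (moles, pigment spots) as connected
components of thresholded level sets whose area is stable across thresholds.

Region semantics (identical to the exhaustive threshold-sweep definition):

* Dark-polarity level sets are ``L_t = {p : I(p) <= t}`` for ``t = 0..255``
  under 4-connectivity; bright polarity runs the same machinery on ``255-I``.
* A *region* is a distinct pixel set occurring as a connected component of
  some ``L_t``; its first level is ``t0``; its *seed* is the pixel minimizing
  ``(intensity, row, col)``.
* The region's variation is ``(A(t0+delta) - A(t0-delta)) / area``, where
  ``A(t)`` is the area of the component containing the seed at level ``t``
  (0 below the seed's intensity; levels clamped to 255 above).
* A region is maximally stable when its variation is <= ``max_variation``,
  no greater than the variation of its chain neighbours (the next distinct
  region containing the seed below and above), and its area lies within
  ``[min_area, max_area]``.

Stability plateaus select every region on the plateau; co-located detections
are deliberately kept and only resolved at the 3-D outlier stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Feature, FeatureEnsemble, Roi

__all__ = ["MserParams", "detect_mser", "mser_regions"]


@dataclass
class MserParams:
    """MSER detector configuration.

    delta : threshold step (levels) used in the stability test.
    min_area, max_area : area bounds in pixels; when ``max_area`` is None it
        defaults to ``max_area_frac`` of the ROI area.
    max_variation : maximum admissible relative area variation.
    polarity : "dark", "bright" or "both".
    """

    delta: int = 2
    min_area: int = 10
    max_area: int | None = None
    max_area_frac: float = 0.01
    max_variation: float = 0.25
    polarity: str = "both"

    def __post_init__(self) -> None:
        if self.delta < 1 or self.min_area < 1 or self.max_variation <= 0:
            raise ValueError("MSER parameters must be positive")
        if self.polarity not in ("dark", "bright", "both"):
            raise ValueError("polarity must be dark|bright|both")


class _Node:
    """One distinct extremal region in the component tree."""

    __slots__ = ("level", "area", "sum_r", "sum_c", "seed", "chain_child",
                 "parent", "delta_pixels", "variation")

    def __init__(self, level, area, sum_r, sum_c, seed, chain_child, delta_pixels):
        self.level = level
        self.area = area
        self.sum_r = sum_r
        self.sum_c = sum_c
        self.seed = seed
        self.chain_child = chain_child  # node index or -1
        self.parent = -1
        self.delta_pixels = delta_pixels  # pixels first finalized in this node
        self.variation = np.inf


def _build_tree(img: np.ndarray) -> list[_Node]:
    """Union-find construction of the distinct-region tree of min-level sets."""
    h, w = img.shape
    n = h * w
    flat = img.ravel()
    order = np.argsort(flat, kind="stable")
    uf = np.full(n, -1, dtype=np.int64)  # -1 inactive, else parent (root: self)
    area = np.zeros(n, dtype=np.int64)
    sum_r = np.zeros(n, dtype=np.int64)
    sum_c = np.zeros(n, dtype=np.int64)
    seed = {}        # root -> (intensity, r, c, idx)
    prev_node = {}   # root -> node index of last finalized set in seed chain
    pending = {}     # root -> node indices awaiting a parent
    delta_px = {}    # root -> pixels not yet assigned to a node
    nodes: list[_Node] = []

    def find(i):
        root = i
        while uf[root] != root:
            root = uf[root]
        while uf[i] != root:
            uf[i], i = root, uf[i]
        return root

    pos = 0
    while pos < n:
        t = flat[order[pos]]
        touched = []
        while pos < n and flat[order[pos]] == t:
            idx = order[pos]
            pos += 1
            r, c = divmod(int(idx), w)
            uf[idx] = idx
            area[idx] = 1
            sum_r[idx] = r
            sum_c[idx] = c
            seed[idx] = (int(t), r, c, int(idx))
            prev_node[idx] = -1
            pending[idx] = []
            delta_px[idx] = [int(idx)]
            touched.append(int(idx))
            for nb in _neighbors(int(idx), r, c, h, w):
                if uf[nb] < 0:
                    continue
                ra, rb = find(int(idx)), find(nb)
                if ra == rb:
                    continue
                # union by size; keep chain state of the winning seed
                if area[ra] < area[rb]:
                    ra, rb = rb, ra
                sa, sb = seed[ra], seed[rb]
                if sb < sa:
                    win_prev, lose_prev = prev_node[rb], prev_node[ra]
                    new_seed = sb
                else:
                    win_prev, lose_prev = prev_node[ra], prev_node[rb]
                    new_seed = sa
                uf[rb] = ra
                area[ra] += area[rb]
                sum_r[ra] += sum_r[rb]
                sum_c[ra] += sum_c[rb]
                seed[ra] = new_seed
                prev_node[ra] = win_prev
                pend = pending[ra]
                pend.extend(pending.pop(rb))
                if lose_prev >= 0:
                    pend.append(lose_prev)
                dp = delta_px[ra]
                dp.extend(delta_px.pop(rb))
                seed.pop(rb, None)
                prev_node.pop(rb, None)
                touched.append(ra)
        # finalize components whose pixel set changed at this level
        roots = {find(i) for i in touched}
        for root in roots:
            node_idx = len(nodes)
            node = _Node(int(t), int(area[root]), int(sum_r[root]),
                         int(sum_c[root]), seed[root], prev_node[root],
                         delta_px[root])
            nodes.append(node)
            if node.chain_child >= 0:
                nodes[node.chain_child].parent = node_idx
            for p in pending[root]:
                nodes[p].parent = node_idx
            pending[root] = []
            prev_node[root] = node_idx
            delta_px[root] = []
    return nodes


def _neighbors(idx, r, c, h, w):
    if r > 0:
        yield idx - w
    if r < h - 1:
        yield idx + w
    if c > 0:
        yield idx - 1
    if c < w - 1:
        yield idx + 1


def _compute_variations(nodes: list[_Node], delta: int) -> None:
    for node in nodes:
        t0 = node.level
        up = min(t0 + delta, 255)
        anc = node
        while anc.parent >= 0 and nodes[anc.parent].level <= up:
            anc = nodes[anc.parent]
        area_up = anc.area
        down = t0 - delta
        if down < node.seed[0]:
            area_down = 0
        else:
            d = node
            while d.level > down:
                d = nodes[d.chain_child]  # chain is contiguous down to seed level
            area_down = d.area
        node.variation = (area_up - area_down) / node.area


def _select(nodes: list[_Node], min_area: int, max_area: int,
            max_variation: float) -> list[int]:
    picked = []
    for i, node in enumerate(nodes):
        if not (min_area <= node.area <= max_area):
            continue
        v = node.variation
        if v > max_variation:
            continue
        if node.parent >= 0 and v > nodes[node.parent].variation:
            continue
        if node.chain_child >= 0 and v > nodes[node.chain_child].variation:
            continue
        picked.append(i)
    return picked


def _collect_pixels(nodes: list[_Node], idx: int) -> list[int]:
    """Reconstruct a node's pixel set from delta pixels in its subtree."""
    children: dict[int, list[int]] = {}
    for j, nd in enumerate(nodes):
        children.setdefault(nd.parent, []).append(j)
    out: list[int] = []
    stack = [idx]
    seen = set()
    while stack:
        j = stack.pop()
        if j in seen:
            continue
        seen.add(j)
        out.extend(nodes[j].delta_pixels)
        stack.extend(k for k in children.get(j, []) if k != j)
    return out


def mser_regions(image: np.ndarray, params: MserParams, polarity: str,
                 max_area: int) -> list[tuple[np.ndarray, float, tuple]]:
    """Run one polarity; returns (pixel rc-array, variation, seed) per region."""
    img = np.asarray(image, dtype=np.uint8)
    work = img if polarity == "dark" else (255 - img)
    nodes = _build_tree(work)
    _compute_variations(nodes, params.delta)
    picked = _select(nodes, params.min_area, max_area, params.max_variation)
    h, w = img.shape
    regions = []
    for i in picked:
        lin = np.array(sorted(_collect_pixels(nodes, i)), dtype=np.int64)
        rc = np.column_stack([lin // w, lin % w])
        regions.append((rc, nodes[i].variation, nodes[i].seed))
    return regions


def detect_mser(image: np.ndarray, roi: Roi | None = None,
                params: MserParams | None = None) -> FeatureEnsemble:
    """Detect MSER blobs inside a ROI of an 8-bit grayscale image.

    Feature locations are region centroids (image coordinates), the scale is
    the equivalent-circle radius ``sqrt(area/pi)`` and the response is the
    negated variation (higher = more stable).
    """
    params = params or MserParams()
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.rint(np.asarray(img, dtype=float)), 0, 255).astype(np.uint8)
    cam_id = roi.camera_id if roi is not None else 0
    if roi is None:
        roi = Roi(cam_id, 0, 0, img.shape[1], img.shape[0])
    roi = roi.clip_to(img.shape)
    sub = img[roi.y:roi.y + roi.height, roi.x:roi.x + roi.width]
    if sub.size == 0:
        return FeatureEnsemble(camera_id=cam_id)
    max_area = params.max_area
    if max_area is None:
        max_area = max(int(params.max_area_frac * sub.size), params.min_area)
    feats = []
    polarities = ("dark", "bright") if params.polarity == "both" else (params.polarity,)
    for pol in polarities:
        sign = -1 if pol == "dark" else +1
        for rc, variation, _seed in mser_regions(sub, params, pol, max_area):
            cy = rc[:, 0].mean() + roi.y
            cx = rc[:, 1].mean() + roi.x
            region = rc + np.array([roi.y, roi.x])
            feats.append(Feature(
                camera_id=cam_id, index=0, x=float(cx), y=float(cy),
                scale=float(np.sqrt(len(rc) / np.pi)), detector="MSER",
                response=float(-variation), polarity=sign,
                region_pixels=region))
    return FeatureEnsemble(camera_id=cam_id, features=feats).reindex()
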