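"""Scan-line SSD matching of descriptor sets between two rectified views.

After rectification, corresponding skin features share a row ("scan line")
up to a small residual, so candidate matches are restricted to a narrow row
band and the sum of squared differences between descriptors decides among
them.  Since descriptors are unit-normalized, ``ssd = 2 (1 - cosine)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DescriptorSet

__all__ = ["MatchParams", "MatchSet", "match_scanline_ssd"]


@dataclass
class MatchParams:
    """Scan-line matcher configuration.

    band : maximum |row_i - row_j| in rectified rows.
    disparity_range : admissible (min, max) of ``x_i - x_j`` in pixels, or
        None for unrestricted (requires x coordinates to be supplied).
    ssd_max : maximum accepted SSD (on unit descriptors, in [0, 4]).
    ratio : best/second-best SSD threshold (Lowe-style); set to 1.0 together
        with ``mutual=False`` to reproduce the bare minimal-SSD rule.
    mutual : require the match to be best in both directions.
    loc_eps : candidates within this distance (px, Chebyshev on (x, row), or
        row only when x is unavailable) of the best candidate count as the
        same physical location and are excluded from the second-best used in
        the ratio test — nested co-located blob detections are deliberately
        kept upstream and must not read as ambiguity.
    """

    band: float = 2.0
    disparity_range: tuple[float, float] | None = None
    ssd_max: float = 1.0
    ratio: float = 0.8
    mutual: bool = True
    loc_eps: float = 1.5


@dataclass
class MatchSet:
    """One-to-one matches between two descriptor sets (0-based indices)."""

    pair: tuple[int, int]
    indices_i: list[int] = field(default_factory=list)
    indices_j: list[int] = field(default_factory=list)
    ssd: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices_i)

    def swapped(self) -> "MatchSet":
        order = np.argsort(self.indices_j, kind="stable")
        return MatchSet(pair=(self.pair[1], self.pair[0]),
                        indices_i=[self.indices_j[k] for k in order],
                        indices_j=[self.indices_i[k] for k in order],
                        ssd=[self.ssd[k] for k in order])


def _best_candidate(cost_row, rows_self, rows_other, cand_mask,
                    x_other=None, loc_eps=0.0):
    """Index of minimal-SSD candidate with deterministic tie-breaking.

    Ties broken by smaller |row difference|, then smaller index.  The
    second-best (for the ratio test) is taken over candidates farther than
    ``loc_eps`` from the best one, so co-located duplicates are ignored.
    """
    idx = np.nonzero(cand_mask)[0]
    if idx.size == 0:
        return -1, np.inf, np.inf
    costs = cost_row[idx]
    rowdiff = np.abs(rows_other[idx] - rows_self)
    order = np.lexsort((idx, rowdiff, costs))
    best = int(idx[order[0]])
    distinct = np.abs(rows_other[idx] - rows_other[best]) > loc_eps
    if x_other is not None:
        distinct |= np.abs(x_other[idx] - x_other[best]) > loc_eps
    second = costs[distinct].min() if distinct.any() else np.inf
    return best, float(cost_row[best]), float(second)


def match_scanline_ssd(set_i: DescriptorSet, set_j: DescriptorSet,
                       params: MatchParams | None = None,
                       x_i: np.ndarray | None = None,
                       x_j: np.ndarray | None = None) -> MatchSet:
    """Match two descriptor sets along epipolar scan lines.

    Candidates must satisfy the row-band constraint (and the disparity range
    when x coordinates are given); each side's minimal-SSD candidate is
    chosen, mutual-best filtering enforces one-to-one matching, and the
    SSD/ratio thresholds reject weak or ambiguous matches.  Zero (constant-
    patch) descriptors never participate.
    """
    params = params or MatchParams()
    if params.band < 0:
        raise ValueError("band must be >= 0")
    pair = (set_i.camera_id, set_j.camera_id)
    out = MatchSet(pair=pair)
    ni, nj = len(set_i), len(set_j)
    if ni == 0 or nj == 0:
        return out
    Di, Dj = set_i.matrix(), set_j.matrix()
    ri, rj = set_i.rows(), set_j.rows()
    ok_i = np.any(Di != 0, axis=1)
    ok_j = np.any(Dj != 0, axis=1)
    cost = ((Di[:, None, :] - Dj[None, :, :]) ** 2).sum(axis=2)
    cand = (np.abs(ri[:, None] - rj[None, :]) <= params.band)
    cand &= ok_i[:, None] & ok_j[None, :]
    if params.disparity_range is not None:
        if x_i is None or x_j is None:
            raise ValueError("disparity_range requires x coordinates")
        disp = np.asarray(x_i)[:, None] - np.asarray(x_j)[None, :]
        cand &= (disp >= params.disparity_range[0]) & (disp <= params.disparity_range[1])

    xi = np.asarray(x_i, dtype=float) if x_i is not None else None
    xj = np.asarray(x_j, dtype=float) if x_j is not None else None
    best_j = np.full(ni, -1, dtype=int)
    ssd_i = np.full(ni, np.inf)
    ratio_ok_i = np.zeros(ni, dtype=bool)
    for i in range(ni):
        b, c, second = _best_candidate(cost[i], ri[i], rj, cand[i],
                                       x_other=xj, loc_eps=params.loc_eps)
        best_j[i] = b
        ssd_i[i] = c
        ratio_ok_i[i] = b >= 0 and (not np.isfinite(second) or c <= params.ratio * second)
    best_i = np.full(nj, -1, dtype=int)
    ratio_ok_j = np.zeros(nj, dtype=bool)
    for j in range(nj):
        b, c, second = _best_candidate(cost[:, j], rj[j], ri, cand[:, j],
                                       x_other=xi, loc_eps=params.loc_eps)
        best_i[j] = b
        ratio_ok_j[j] = b >= 0 and (not np.isfinite(second) or c <= params.ratio * second)

    for i in range(ni):
        j = best_j[i]
        if j < 0 or ssd_i[i] > params.ssd_max:
            continue
        if params.mutual and best_i[j] != i:
            continue
        if not (ratio_ok_i[i] and ratio_ok_j[j]):
            continue
        assert abs(ri[i] - rj[j]) <= params.band
        out.indices_i.append(i)
        out.indices_j.append(j)
        out.ssd.append(float(cost[i, j]))
    return out
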