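"""Scan-line SSD matching vs an exhaustive all-pairs oracle."""

import numpy as np
import pytest

import skinloc as sl
from skinloc.features import Descriptor, DescriptorSet
from skinloc.matching import MatchParams, match_scanline_ssd


def make_set(vectors, rows, camera_id=1):
    descs = [Descriptor(vector=np.asarray(v, dtype=float), y_row=float(r))
             for v, r in zip(vectors, rows)]
    return DescriptorSet(camera_id=camera_id, descriptors=descs)


def random_set(rng, n, camera_id, rows=None):
    vecs = rng.normal(size=(n, 64))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    if rows is None:
        rows = rng.uniform(0, 50, size=n)
    return make_set(vecs, rows, camera_id)


def oracle_match(set_i, set_j, params, x_i=None, x_j=None):
    """Enumerate all pairs; apply band/disparity, mutual-best and two-sided
    location-aware ratio rules exactly as specified, with loops."""
    ni, nj = len(set_i), len(set_j)
    Di, Dj = set_i.matrix(), set_j.matrix()
    ri, rj = set_i.rows(), set_j.rows()

    def cand_ij(i, j):
        if not np.any(Di[i]) or not np.any(Dj[j]):
            return False
        if abs(ri[i] - rj[j]) > params.band:
            return False
        if params.disparity_range is not None:
            d = x_i[i] - x_j[j]
            if not (params.disparity_range[0] <= d <= params.disparity_range[1]):
                return False
        return True

    cost = np.array([[((Di[i] - Dj[j]) ** 2).sum() for j in range(nj)]
                     for i in range(ni)])

    def best(i, axis):
        cands = [j for j in range(nj if axis == 0 else ni)
                 if (cand_ij(i, j) if axis == 0 else cand_ij(j, i))]
        if not cands:
            return None, np.inf, np.inf
        if axis == 0:
            key = lambda j: (cost[i, j], abs(rj[j] - ri[i]), j)
            rows_o, x_o = rj, x_j
        else:
            key = lambda j: (cost[j, i], abs(ri[j] - rj[i]), j)
            rows_o, x_o = ri, x_i
        b = min(cands, key=key)
        distinct = [j for j in cands
                    if abs(rows_o[j] - rows_o[b]) > params.loc_eps
                    or (x_o is not None and abs(x_o[j] - x_o[b]) > params.loc_eps)]
        second = min((cost[i, j] if axis == 0 else cost[j, i])
                     for j in distinct) if distinct else np.inf
        c = cost[i, b] if axis == 0 else cost[b, i]
        return b, c, second

    matches = []
    for i in range(ni):
        j, c, sec_i = best(i, axis=0)
        if j is None or c > params.ssd_max:
            continue
        i_back, c2, sec_j = best(j, axis=1)
        if params.mutual and i_back != i:
            continue
        ok_i = not np.isfinite(sec_i) or c <= params.ratio * sec_i
        ok_j = not np.isfinite(sec_j) or c2 <= params.ratio * sec_j
        if not (ok_i and ok_j):
            continue
        matches.append((i, j, c))
    return matches


def test_self_match_is_identity_with_zero_ssd():
    rng = np.random.default_rng(0)
    s = random_set(rng, 12, 1)
    ms = match_scanline_ssd(s, s, MatchParams(band=0.5))
    assert ms.indices_i == ms.indices_j == list(range(12))
    assert all(v == 0.0 for v in ms.ssd)


def test_band_excludes_distant_rows():
    rng = np.random.default_rng(1)
    v = rng.normal(size=64)
    v /= np.linalg.norm(v)
    set_i = make_set([v, v], rows=[100.0, 400.0], camera_id=1)
    set_j = make_set([v], rows=[100.0], camera_id=2)
    ms = match_scanline_ssd(set_i, set_j, MatchParams(band=2.0))
    assert len(ms) == 1
    assert ms.indices_i == [0] and ms.indices_j == [0]


@pytest.mark.parametrize("seed", range(8))
def test_matches_exhaustive_oracle_on_random_sets(seed):
    rng = np.random.default_rng(seed)
    si = random_set(rng, 20, 1)
    sj = random_set(rng, 20, 2)
    xi = rng.uniform(0, 100, 20)
    xj = rng.uniform(0, 100, 20)
    params = MatchParams(band=3.0, ssd_max=4.0, ratio=0.95,
                         disparity_range=(-100.0, 100.0))
    ms = match_scanline_ssd(si, sj, params, x_i=xi, x_j=xj)
    got = list(zip(ms.indices_i, ms.indices_j, ms.ssd))
    want = oracle_match(si, sj, params, x_i=xi, x_j=xj)
    assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in want]
    np.testing.assert_allclose([c for *_, c in got], [c for *_, c in want],
                               atol=1e-12)


def test_no_band_violations_ever():
    rng = np.random.default_rng(5)
    for _ in range(5):
        si = random_set(rng, 15, 1)
        sj = random_set(rng, 15, 2)
        ms = match_scanline_ssd(si, sj, MatchParams(band=2.0, ssd_max=4.0))
        ri, rj = si.rows(), sj.rows()
        for i, j in zip(ms.indices_i, ms.indices_j):
            assert abs(ri[i] - rj[j]) <= 2.0


def test_symmetry_under_set_swap():
    rng = np.random.default_rng(6)
    si = random_set(rng, 18, 1)
    sj = random_set(rng, 18, 2)
    params = MatchParams(band=3.0, ssd_max=4.0, ratio=0.9)
    fw = match_scanline_ssd(si, sj, params)
    bw = match_scanline_ssd(sj, si, params)
    assert set(zip(fw.indices_i, fw.indices_j)) == \
        set(zip(bw.indices_j, bw.indices_i))


def test_zero_descriptors_never_match():
    rng = np.random.default_rng(7)
    si = random_set(rng, 5, 1, rows=[10, 11, 12, 13, 14])
    sj = random_set(rng, 5, 2, rows=[10, 11, 12, 13, 14])
    si.descriptors[2] = sl.Descriptor(vector=np.zeros(64), y_row=12.0)
    ms = match_scanline_ssd(si, sj, MatchParams(band=5.0, ssd_max=4.0, ratio=1.0))
    assert 2 not in ms.indices_i


def test_band_restriction_never_worsens_accepted_ssd():
    # accepted matches under the band cannot have higher SSD than the
    # unrestricted (infinite-band) choice for the same feature
    rng = np.random.default_rng(8)
    si = random_set(rng, 20, 1)
    sj = random_set(rng, 20, 2)
    narrow = match_scanline_ssd(si, sj, MatchParams(band=2.0, ssd_max=4.0, ratio=1.0))
    wide = match_scanline_ssd(si, sj, MatchParams(band=1e9, ssd_max=4.0, ratio=1.0))
    wide_best = dict(zip(wide.indices_i, wide.ssd))
    for i, c in zip(narrow.indices_i, narrow.ssd):
        if i in wide_best:
            assert c >= wide_best[i] - 1e-12


def test_simulator_matching_precision(default_scene):
    """On rendered pairs, >=90% of accepted matches link the same blob."""
    cfg, rig, images, gt = default_scene
    import dataclasses
    from skinloc.fast_hessian import extract_descriptors
    from skinloc.pipeline import _detect, _map_roi

    pcfg = sl.PipelineConfig(seed=0, detector="mser")
    rect = sl.rectify_pair(images[2], images[3], rig[1], rig[2])
    roi = sl.Roi(2, 8, 8, images[2].shape[1] - 16, images[2].shape[0] - 16)
    roi_i = _map_roi(roi, rect.homographies[0], rect.images[0].shape)
    roi_j = _map_roi(dataclasses.replace(roi, camera_id=3),
                     rect.homographies[1], rect.images[1].shape)
    ens_i, d_i = extract_descriptors(rect.images[0],
                                     _detect(rect.images[0], roi_i, "MSER", pcfg))
    ens_j, d_j = extract_descriptors(rect.images[1],
                                     _detect(rect.images[1], roi_j, "MSER", pcfg))
    ms = match_scanline_ssd(d_i, d_j, pcfg.match,
                            x_i=ens_i.locations()[:, 0],
                            x_j=ens_j.locations()[:, 0])
    assert len(ms) >= 10
    proj_i = rect.to_rectified(0, gt.blob_projections[2])
    proj_j = rect.to_rectified(1, gt.blob_projections[3])

    def blob_of(px, proj):
        d = np.linalg.norm(proj - px, axis=1)
        return int(d.argmin()) if d.min() < 4.0 else -1

    correct = total = 0
    for i, j in zip(ms.indices_i, ms.indices_j):
        bi = blob_of(ens_i.locations()[i], proj_i)
        bj = blob_of(ens_j.locations()[j], proj_j)
        if bi >= 0 or bj >= 0:
            total += 1
            correct += (bi == bj and bi >= 0)
    assert total > 0
    assert correct / total >= 0.9
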