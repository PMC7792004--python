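"""Shared fixtures: synthetic rigs, scenes, and small test images."""

from __future__ import annotations

import numpy as np
import pytest

import skinloc as sl


@pytest.fixture(scope="session")
def default_scene():
    """Noiseless default scene: rig, images, ground truth (rendered once)."""
    cfg = sl.SceneConfig(seed=7)
    rig = sl.make_rig(cfg)
    images, gt = sl.render(cfg, rig)
    return cfg, rig, images, gt


@pytest.fixture(scope="session")
def small_rig():
    """Two-camera convergent rig for geometry tests."""
    cfg = sl.SceneConfig.compact(seed=1)
    return sl.make_rig(cfg)[:2]


def make_translation_pair(baseline=50.0, focal=800.0, size=(640, 480)):
    """Identical-intrinsics cameras related by pure x-translation."""
    w, h = size
    cams = []
    for i, cx_off in enumerate((0.0, baseline)):
        cams.append(sl.CameraModel(
            camera_id=i + 1, focal=(focal, focal),
            principal_point=((w - 1) / 2, (h - 1) / 2),
            rotation=np.eye(3),
            translation=np.array([-cx_off, 0.0, 0.0])))
    return cams


def disc_image(shape=(32, 32), center=(15.5, 15.5), radius=6.0,
               fg=40, bg=200, supersample=8):
    """Anti-aliased disc on constant background (uint8)."""
    h, w = shape
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = (np.arange(h)[:, None] + off[None, :]).ravel()
    xs = (np.arange(w)[:, None] + off[None, :]).ravel()
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius ** 2
    cov = inside.reshape(h, supersample, w, supersample).mean(axis=(1, 3))
    return np.clip(np.rint(bg * (1 - cov) + fg * cov), 0, 255).astype(np.uint8)


def gaussian_blob_image(shape=(32, 32), center=(16.0, 16.0), sigma=3.0,
                        depth=140.0, bg=200.0):
    """Dark Gaussian blob on constant background (float, 8-bit range)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    g = np.exp(-(((x - center[0]) ** 2 + (y - center[1]) ** 2)
                 / (2 * sigma ** 2)))
    return bg - depth * g
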