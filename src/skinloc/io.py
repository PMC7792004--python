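"""File exchange: images, feature/match tables, ROI files, point clouds.

Formats match what the pipeline stages consume and emit: 8-bit grayscale
PNG/TIFF images, JSON calibration and ROI files, CSV tables for features,
matches and statistics, and ASCII PLY clouds with per-vertex triangulation
error.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FeatureEnsemble, Roi
from .matching import MatchSet
from .triangulation import TriangulationSet

__all__ = ["read_image", "write_image", "load_rois", "save_rois",
           "features_to_frame", "matches_to_frame", "write_ply",
           "triangulation_to_frame"]


def read_image(path) -> np.ndarray:
    """Read an image as 8-bit grayscale (averages channels if needed)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def load_rois(path) -> list[Roi]:
    """ROI file: JSON list of {camera_id, x, y, w, h}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [Roi(r["camera_id"], r["x"], r["y"], r["w"], r["h"]) for r in raw]


def save_rois(rois: list[Roi], path) -> None:
    with open(path, "w") as fh:
        json.dump([{"camera_id": r.camera_id, "x": r.x, "y": r.y,
                    "w": r.width, "h": r.height} for r in rois], fh, indent=1)


def features_to_frame(ensemble: FeatureEnsemble) -> pd.DataFrame:
    return pd.DataFrame([{
        "camera_id": f.camera_id, "index": f.index, "x": f.x, "y": f.y,
        "scale": f.scale, "detector": f.detector, "response": f.response,
    } for f in ensemble])


def matches_to_frame(ms: MatchSet, rows_i, rows_j) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": f"c{ms.pair[0]}|c{ms.pair[1]}",
        "index_i": i, "index_j": j,
        "row_i": rows_i[i], "row_j": rows_j[j], "ssd": s,
    } for i, j, s in zip(ms.indices_i, ms.indices_j, ms.ssd)])


def triangulation_to_frame(ts: TriangulationSet) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": f"c{ts.pair[0]}|c{ts.pair[1]}", "index": f.index,
        "x_mm": f.x, "y_mm": f.y, "z_mm": f.z, "e_mm": f.e,
    } for f in ts])


def write_ply(path, points: np.ndarray, errors: np.ndarray | None = None) -> None:
    """ASCII PLY cloud (mm) with optional per-vertex triangulation error."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if errors is not None:
            fh.write("property float triangulation_error\n")
        fh.write("end_header\n")
        for k, p in enumerate(pts):
            line = f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            if errors is not None:
                line += f" {float(errors[k]):.6f}"
            fh.write(line + "\n")
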