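"""Descriptive statistics of triangulation errors per analyzed region.

Mirrors the reporting schema used for clinical skin-feature localization:
per-region mean / std / RMS / min / quartiles / max of the triangulation
error (mm), the analyzed area (cm^2), feature density (features per cm^2)
and the discard ratio of matched features to surviving inliers.  Quartiles
use linear interpolation between order statistics (Hyndman-Fan type 7).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["RegionStats", "compute_region_stats", "aggregate_regions",
           "describe"]


def describe(values) -> dict:
    """Marker-style descriptive summary: mean/std/rms/min/quartiles/max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("nothing to describe")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "mean_mm": float(v.mean()),
        "std_mm": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "rms_mm": float(np.sqrt((v ** 2).mean())),
        "min_mm": float(v.min()),
        "q1_mm": float(q1),
        "median_mm": float(med),
        "q3_mm": float(q3),
        "max_mm": float(v.max()),
    }


@dataclass
class RegionStats:
    region_id: str
    area_cm2: float
    n_features: int
    features_per_cm2: float
    mean_mm: float
    std_mm: float
    rms_mm: float
    min_mm: float
    q1_mm: float
    median_mm: float
    q3_mm: float
    max_mm: float
    discard_ratio: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_region_stats(errors, area_cm2: float, matched_count: int,
                         region_id: str = "region") -> RegionStats:
    """Summarize one region's triangulation errors.

    ``errors`` are the inlier triangulation errors in mm; ``matched_count``
    the number of matched features before 3-D outlier removal.  Sample
    standard deviation (ddof=1; 0 for a single feature), RMS is
    ``sqrt(mean(e^2))``.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("no errors to summarize")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    q1, med, q3 = np.percentile(e, [25, 50, 75])  # linear interpolation (type 7)
    return RegionStats(
        region_id=region_id,
        area_cm2=float(area_cm2),
        n_features=int(e.size),
        features_per_cm2=float(e.size / area_cm2),
        mean_mm=float(e.mean()),
        std_mm=float(e.std(ddof=1)) if e.size > 1 else 0.0,
        rms_mm=float(np.sqrt((e ** 2).mean())),
        min_mm=float(e.min()),
        q1_mm=float(q1),
        median_mm=float(med),
        q3_mm=float(q3),
        max_mm=float(e.max()),
        discard_ratio=float(matched_count / e.size),
    )


def aggregate_regions(per_region_errors: list[np.ndarray],
                      per_region_areas: list[float],
                      per_region_matched: list[int]) -> RegionStats:
    """Pooled "TOT" statistics: recomputed over the concatenated errors.

    Areas sum; the discard ratio uses total matched over total inliers, so
    the aggregate equals a recomputation on the pooled vectors rather than
    an average of per-region summaries.
    """
    pooled = np.concatenate([np.asarray(e, dtype=float)
                             for e in per_region_errors])
    return compute_region_stats(pooled, float(np.sum(per_region_areas)),
                                int(np.sum(per_region_matched)),
                                region_id="TOT")
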