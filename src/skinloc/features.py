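"""Domain containers for detected skin features and their descriptors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Roi", "Feature", "FeatureEnsemble", "Descriptor", "DescriptorSet"]


@dataclass
class Roi:
    """Rectangular region of interest in one camera's image (pixels)."""

    camera_id: int
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width/height must be positive")

    def clip_to(self, shape) -> "Roi":
        h, w = shape
        x0 = max(int(self.x), 0)
        y0 = max(int(self.y), 0)
        x1 = min(int(self.x + self.width), w)
        y1 = min(int(self.y + self.height), h)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("ROI lies outside the image")
        return Roi(self.camera_id, x0, y0, x1 - x0, y1 - y0)

    def contains(self, x: float, y: float) -> bool:
        return (self.x <= x < self.x + self.width
                and self.y <= y < self.y + self.height)


@dataclass
class Feature:
    """A detected blob-like skin feature.

    ``location`` is the sub-pixel (x, y); ``scale`` the characteristic radius
    in pixels; ``detector`` one of ``{"MSER", "SURF"}``; ``region_pixels`` the
    supporting pixel set (MSER only); ``polarity`` +1 for bright-on-dark and
    -1 for dark-on-bright blobs.
    """

    camera_id: int
    index: int
    x: float
    y: float
    scale: float
    detector: str
    response: float = 0.0
    polarity: int = -1
    region_pixels: np.ndarray | None = None

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class FeatureEnsemble:
    """Ordered collection of features from one camera (one detector run)."""

    camera_id: int
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    def locations(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, 2))
        return np.array([[f.x, f.y] for f in self.features])

    def reindex(self) -> "FeatureEnsemble":
        """Sort by (y, x, scale) and assign contiguous 1-based indices."""
        feats = sorted(self.features, key=lambda f: (f.y, f.x, f.scale))
        for n, f in enumerate(feats, start=1):
            f.index = n
        return FeatureEnsemble(camera_id=self.camera_id, features=feats)


@dataclass
class Descriptor:
    """64-d upright SURF-style vector plus the feature's (rectified) row."""

    vector: np.ndarray
    y_row: float

    @property
    def is_unmatchable(self) -> bool:
        """True for the zero descriptor (feature on a constant patch)."""
        return not np.any(self.vector)


@dataclass
class DescriptorSet:
    """Descriptors aligned index-for-index with a FeatureEnsemble."""

    camera_id: int
    descriptors: list[Descriptor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i: int) -> Descriptor:
        return self.descriptors[i]

    def matrix(self) -> np.ndarray:
        if not self.descriptors:
            return np.zeros((0, 64))
        return np.vstack([d.vector for d in self.descriptors])

    def rows(self) -> np.ndarray:
        return np.array([d.y_row for d in self.descriptors])
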