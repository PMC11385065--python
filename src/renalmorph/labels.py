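"""Semantic class labels and the per-pixel label map.

The segmenter only ever emits the three structure classes (glomeruli,
tubuli, arteries). Stroma, the proper stromal rim and infiltration are
derived downstream; background is everything outside tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .config import PixelCalibration

__all__ = ["ClassLabel", "STRUCTURE_CLASSES", "DERIVED_CLASSES", "LabelMap", "OVERLAY_PALETTE"]


class ClassLabel(IntEnum):
    """Closed label set of the pipeline (integer codes index rasters)."""

    background = 0
    glomeruli = 1
    tubuli = 2
    arteries = 3
    stroma = 4
    proper_stroma = 5
    infiltration = 6


#: Classes a segmenter may emit.
STRUCTURE_CLASSES = (ClassLabel.glomeruli, ClassLabel.tubuli, ClassLabel.arteries)
#: Classes derived by the pipeline, never emitted by a segmenter.
DERIVED_CLASSES = (ClassLabel.stroma, ClassLabel.proper_stroma, ClassLabel.infiltration)

#: Display palette matching the pipeline's visual convention:
#: glomeruli orange, tubules blue, arteries green, stroma grey,
#: proper stromal space light blue, infiltration brown.
OVERLAY_PALETTE: dict[ClassLabel, tuple[int, int, int]] = {
    ClassLabel.background: (255, 255, 255),
    ClassLabel.glomeruli: (255, 165, 0),
    ClassLabel.tubuli: (65, 105, 225),
    ClassLabel.arteries: (60, 179, 113),
    ClassLabel.stroma: (150, 150, 150),
    ClassLabel.proper_stroma: (173, 216, 230),
    ClassLabel.infiltration: (139, 69, 19),
}


@dataclass
class LabelMap:
    """Per-pixel semantic classes over a tile or slide region.

    Attributes
    ----------
    raster : ndarray of uint8, shape (H, W)
        ``ClassLabel`` codes; every pixel has exactly one label.
    calibration : PixelCalibration
    origin : (int, int)
        Slide-coordinate (x, y) offset of raster pixel (0, 0).
    """

    raster: np.ndarray
    calibration: PixelCalibration
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.uint8)
        valid = np.isin(self.raster, [int(c) for c in ClassLabel])
        if not valid.all():
            bad = sorted(set(np.unique(self.raster[~valid]).tolist()))
            raise ValueError(f"raster contains non-label codes: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    def mask(self, *labels: ClassLabel) -> np.ndarray:
        """Boolean mask of pixels carrying any of the given labels."""
        out = np.zeros(self.raster.shape, dtype=bool)
        for lab in labels:
            out |= self.raster == int(lab)
        return out

    def class_areas_px(self) -> dict[ClassLabel, int]:
        """Pixel count per class; values sum to the raster size."""
        counts = np.bincount(self.raster.ravel(), minlength=len(ClassLabel))
        return {lab: int(counts[int(lab)]) for lab in ClassLabel}

    def class_areas_um2(self) -> dict[ClassLabel, float]:
        s2 = self.calibration.pixel_size_um**2
        return {lab: n * s2 for lab, n in self.class_areas_px().items()}

    def to_rgb(self, palette: dict[ClassLabel, tuple[int, int, int]] | None = None) -> np.ndarray:
        """Render the label map as an RGB image using the overlay palette."""
        palette = palette or OVERLAY_PALETTE
        lut = np.zeros((256, 3), dtype=np.uint8)
        for lab, rgb in palette.items():
            lut[int(lab)] = rgb
        return lut[self.raster]
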