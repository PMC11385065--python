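"""Instance masks and basic area arithmetic.

An :class:`InstanceMask` stores its binary raster cropped to a tight,
half-open bounding box ``(x0, y0, x1, y1)`` in slide coordinates (x is the
column axis), which keeps whole-slide instance lists small. Overlap
statistics (IoU, intersection-over-minimum) work on the bbox intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import ClassLabel, STRUCTURE_CLASSES

__all__ = ["InstanceMask", "area_fraction", "mask_iou", "mask_iomin"]


class MaskContainmentError(ValueError):
    """mask_a is not contained in mask_total."""


@dataclass
class InstanceMask:
    """One segmented tissue structure.

    Attributes
    ----------
    class_label : ClassLabel
        One of the structure classes (glomeruli/tubuli/arteries).
    mask : ndarray of bool, shape (y1-y0, x1-x0)
        Binary raster cropped to ``bbox``; nonempty.
    bbox : (x0, y0, x1, y1)
        Tight half-open bounds of the mask in slide coordinates.
    score : float
        Segmenter confidence in [0, 1].
    """

    class_label: ClassLabel
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    score: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.class_label not in STRUCTURE_CLASSES:
            raise ValueError(
                f"instances carry structure classes only, got {self.class_label!r}"
            )
        if not self.mask.any():
            raise ValueError("instance mask is empty")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        x0, y0, x1, y1 = self.bbox
        if self.mask.shape != (y1 - y0, x1 - x0):
            raise ValueError("mask shape does not match bbox")
        ys, xs = np.nonzero(self.mask)
        if ys.min() != 0 or xs.min() != 0 or ys.max() != self.mask.shape[0] - 1 or xs.max() != self.mask.shape[1] - 1:
            raise ValueError("bbox is not tight around the mask")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_full_mask(
        cls,
        class_label: ClassLabel,
        full_mask: np.ndarray,
        score: float = 1.0,
        origin: tuple[int, int] = (0, 0),
    ) -> "InstanceMask":
        """Build from an uncropped raster; ``origin`` is its (x, y) offset."""
        full_mask = np.asarray(full_mask, dtype=bool)
        ys, xs = np.nonzero(full_mask)
        if ys.size == 0:
            raise ValueError("instance mask is empty")
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        ox, oy = origin
        return cls(
            class_label=class_label,
            mask=full_mask[y0:y1, x0:x1].copy(),
            bbox=(x0 + ox, y0 + oy, x1 + ox, y1 + oy),
            score=score,
        )

    # -- geometry ----------------------------------------------------------

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px * pixel_size_um**2

    def translated(self, dx: int, dy: int) -> "InstanceMask":
        x0, y0, x1, y1 = self.bbox
        return InstanceMask(self.class_label, self.mask, (x0 + dx, y0 + dy, x1 + dx, y1 + dy), self.score)

    def clipped(self, box: tuple[int, int, int, int]) -> "InstanceMask | None":
        """Intersection with a half-open box; None when empty."""
        bx0, by0, bx1, by1 = box
        x0, y0, x1, y1 = self.bbox
        cx0, cy0 = max(x0, bx0), max(y0, by0)
        cx1, cy1 = min(x1, bx1), min(y1, by1)
        if cx0 >= cx1 or cy0 >= cy1:
            return None
        sub = self.mask[cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0]
        if not sub.any():
            return None
        return InstanceMask.from_full_mask(self.class_label, sub, self.score, origin=(cx0, cy0))

    def paint(self, raster: np.ndarray, value: int | bool = True, origin: tuple[int, int] = (0, 0)) -> None:
        """Write the instance into a full raster whose pixel (0,0) sits at ``origin``."""
        ox, oy = origin
        x0, y0, x1, y1 = self.bbox
        h, w = raster.shape[:2]
        rx0, ry0 = max(x0 - ox, 0), max(y0 - oy, 0)
        rx1, ry1 = min(x1 - ox, w), min(y1 - oy, h)
        if rx0 >= rx1 or ry0 >= ry1:
            return
        sub = self.mask[ry0 - (y0 - oy) : ry1 - (y0 - oy), rx0 - (x0 - ox) : rx1 - (x0 - ox)]
        region = raster[ry0:ry1, rx0:rx1]
        region[sub] = value

    def touches_box_border(self, box: tuple[int, int, int, int]) -> bool:
        """True when the instance reaches the border of a half-open box."""
        x0, y0, x1, y1 = self.bbox
        bx0, by0, bx1, by1 = box
        return x0 <= bx0 or y0 <= by0 or x1 >= bx1 or y1 >= by1


def _intersection_px(a: InstanceMask, b: InstanceMask) -> int:
    ax0, ay0, ax1, ay1 = a.bbox
    bx0, by0, bx1, by1 = b.bbox
    cx0, cy0 = max(ax0, bx0), max(ay0, by0)
    cx1, cy1 = min(ax1, bx1), min(ay1, by1)
    if cx0 >= cx1 or cy0 >= cy1:
        return 0
    sub_a = a.mask[cy0 - ay0 : cy1 - ay0, cx0 - ax0 : cx1 - ax0]
    sub_b = b.mask[cy0 - by0 : cy1 - by0, cx0 - bx0 : cx1 - bx0]
    return int(np.logical_and(sub_a, sub_b).sum())


def mask_iou(a: InstanceMask, b: InstanceMask) -> float:
    """Intersection over union of two instances."""
    inter = _intersection_px(a, b)
    if inter == 0:
        return 0.0
    return inter / (a.area_px + b.area_px - inter)


def mask_iomin(a: InstanceMask, b: InstanceMask) -> float:
    """Intersection over the smaller instance's area.

    The merge criterion for same-class fragments: a window fragment that is
    mostly contained in a neighbouring window's larger fragment scores high
    even when the plain IoU is diluted by the larger mask.
    """
    inter = _intersection_px(a, b)
    if inter == 0:
        return 0.0
    return inter / min(a.area_px, b.area_px)


def area_fraction(mask_a: np.ndarray, mask_total: np.ndarray) -> float:
    """Relative area of ``mask_a`` within ``mask_total``, in percent.

    ``mask_a`` must be contained in ``mask_total`` (pixelwise); the
    denominator must be nonempty.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_total = np.asarray(mask_total, dtype=bool)
    if mask_a.shape != mask_total.shape:
        raise ValueError("masks must have the same shape")
    total = int(mask_total.sum())
    if total == 0:
        raise ZeroDivisionError("area_fraction denominator mask is empty")
    if np.logical_and(mask_a, ~mask_total).any():
        raise MaskContainmentError("mask_a is not contained in mask_total")
    return 100.0 * int(mask_a.sum()) / total
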