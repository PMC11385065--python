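"""Slide-analysis orchestration.

The segmenter is pluggable: any callable ``segmenter(tile_rgb, calibration,
box)`` returning a list of :class:`~renalmorph.masks.InstanceMask` in tile
coordinates honors the contract (``box`` gives the tile's half-open slide
coordinates so oracle segmenters can look up ground truth; learned
segmenters may ignore it). The pipeline itself does tissue detection, the
50 µm sliding-window scan with discard of small border fragments, merging
of same-class fragments with strong intersection, and derivation of the
stroma compartments.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .config import PipelineConfig, PixelCalibration, microns_to_pixels
from .geometry import RoiPolygon
from .labels import ClassLabel, LabelMap, STRUCTURE_CLASSES
from .masks import InstanceMask, mask_iomin

__all__ = [
    "Segmenter",
    "detect_tissue",
    "scan_slide",
    "merge_instances",
    "derive_stroma",
    "DegenerateHistogramError",
    "EmptyRegionError",
    "TilingError",
]

Segmenter = Callable[[np.ndarray, PixelCalibration, tuple[int, int, int, int]], list[InstanceMask]]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding requested on an image with a single gray level."""


class EmptyRegionError(ValueError):
    """The analysis region contains no tissue."""


class TilingError(ValueError):
    """Sliding window does not fit the image."""


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Standard luminance transform to the 0-255 gray scale (float)."""
    rgb = np.asarray(rgb)
    if rgb.ndim == 2:
        return rgb.astype(float)
    return rgb2gray(rgb) * 255.0


def detect_tissue(rgb: np.ndarray, threshold: float | str = 230.0) -> np.ndarray:
    """Primary tissue segmentation by light-intensity thresholding.

    A pixel belongs to tissue iff its grayscale luminance is below the
    threshold (background on a scanned slide is near-white). ``threshold``
    is a gray value in (0, 255] or ``"otsu"``.
    """
    gray = to_grayscale(rgb)
    if gray.size == 0:
        raise ValueError("empty image")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        if np.ptp(gray) == 0:
            raise DegenerateHistogramError(
                "cannot Otsu-threshold an image with a single gray level"
            )
        threshold = threshold_otsu(gray)
    return gray < float(threshold)


def _window_starts(a0: int, a1: int, w: int, limit: int) -> list[int]:
    """Start offsets of w-wide windows covering [a0, a1) at ~50% overlap."""
    stride = max(w // 2, 1)
    starts = list(range(a0, max(a1 - w, a0) + 1, stride))
    if starts[-1] + w < a1:
        starts.append(min(a1 - w, limit - w))
    # clamp into the image
    starts = sorted({min(max(s, 0), limit - w) for s in starts})
    return starts


def scan_slide(
    rgb: np.ndarray,
    tissue_mask: np.ndarray,
    segmenter: Segmenter,
    config: PipelineConfig,
    calibration: PixelCalibration,
) -> list[InstanceMask]:
    """Run the segmenter over a sliding window covering the tissue.

    Windows of ``config.window_um`` tile the tissue bounding box with 50 %
    overlap. Within each window, instances that touch the window border and
    are smaller than ``config.border_discard_area_um2`` are discarded as
    unstable fragments (a neighbouring window sees them in its interior).
    Surviving instances are translated to slide coordinates; callers merge
    them with :func:`merge_instances`.
    """
    h, w_img = tissue_mask.shape
    w = microns_to_pixels(config.window_um, calibration)
    if w > h or w > w_img:
        raise TilingError(f"window of {w} px exceeds image of {h}x{w_img}")
    ys, xs = np.nonzero(tissue_mask)
    if ys.size == 0:
        return []
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    out: list[InstanceMask] = []
    min_area_px = config.border_discard_area_um2 / calibration.pixel_size_um**2
    for wy in _window_starts(y0, y1, w, h):
        for wx in _window_starts(x0, x1, w, w_img):
            box = (wx, wy, wx + w, wy + w)
            if not tissue_mask[wy : wy + w, wx : wx + w].any():
                continue
            tile = rgb[wy : wy + w, wx : wx + w]
            for inst in segmenter(tile, calibration, box):
                if inst.class_label not in STRUCTURE_CLASSES:
                    raise ValueError(
                        f"segmenter emitted non-structure class {inst.class_label!r}"
                    )
                if inst.touches_box_border((0, 0, w, w)) and inst.area_px < min_area_px:
                    continue
                out.append(inst.translated(wx, wy))
    return out


def _candidate_pairs(instances: Sequence[InstanceMask]) -> list[tuple[int, int]]:
    """Index pairs of same-class instances with intersecting bboxes."""
    if len(instances) < 2:
        return []
    boxes = np.array([inst.bbox for inst in instances])
    labels = np.array([int(inst.class_label) for inst in instances])
    pairs = []
    order = np.argsort(boxes[:, 0], kind="stable")
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if boxes[j, 0] >= boxes[i, 2]:
                break
            if labels[i] != labels[j]:
                continue
            if boxes[j, 1] < boxes[i, 3] and boxes[i, 1] < boxes[j, 3]:
                pairs.append((int(i), int(j)))
    return pairs


def merge_instances(
    instances: Sequence[InstanceMask],
    iomin_min: float = 0.5,
    overlap=mask_iomin,
) -> list[InstanceMask]:
    """Merge same-class instances with a strong intersection.

    Two instances intersect strongly when ``overlap`` (default:
    intersection over the smaller area) reaches ``iomin_min``. Merging is
    transitive — connected components of the strong-intersection graph are
    unioned — so a chain of window fragments of one structure collapses to a
    single instance. Idempotent and order-independent; the result is sorted
    canonically by (class, y0, x0) and merged scores take the max over
    parents.
    """
    if not (0 < iomin_min <= 1):
        raise ValueError(f"iomin_min must be in (0, 1], got {iomin_min}")
    instances = list(instances)
    parent = list(range(len(instances)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in _candidate_pairs(instances):
        if find(i) != find(j) and overlap(instances[i], instances[j]) >= iomin_min:
            parent[find(i)] = find(j)

    groups: dict[int, list[InstanceMask]] = {}
    for i, inst in enumerate(instances):
        groups.setdefault(find(i), []).append(inst)

    merged: list[InstanceMask] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        x0 = min(m.bbox[0] for m in members)
        y0 = min(m.bbox[1] for m in members)
        x1 = max(m.bbox[2] for m in members)
        y1 = max(m.bbox[3] for m in members)
        union = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        for m in members:
            m.paint(union, True, origin=(x0, y0))
        merged.append(
            InstanceMask.from_full_mask(
                members[0].class_label,
                union,
                score=max(m.score for m in members),
                origin=(x0, y0),
            )
        )
    merged.sort(key=lambda m: (int(m.class_label), m.bbox[1], m.bbox[0], m.bbox[3], m.bbox[2]))
    return merged


def derive_stroma(
    tissue_mask: np.ndarray,
    instances: Sequence[InstanceMask],
    roi: RoiPolygon | np.ndarray | None,
    config: PipelineConfig,
    calibration: PixelCalibration,
) -> LabelMap:
    """Assign every ROI pixel a semantic class, deriving the stroma.

    Tissue not covered by any structure instance is stroma. The proper
    stromal space — the thin physiologic rim (``proper_stroma_width_um``,
    15–20 µm) hugging each structure — is split off by Euclidean-distance
    dilation of the structure union; it is excluded later from fibrosis
    accounting. The remaining stroma is the fibrosis-eligible compartment.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if roi is None:
        roi_mask = np.ones_like(tissue_mask)
    elif isinstance(roi, RoiPolygon):
        roi_mask = roi.to_mask(tissue_mask.shape)
    else:
        roi_mask = np.asarray(roi, dtype=bool)
    region = roi_mask & tissue_mask
    if not region.any():
        raise EmptyRegionError("ROI contains no tissue")

    raster = np.zeros(tissue_mask.shape, dtype=np.uint8)
    structure_union = np.zeros(tissue_mask.shape, dtype=bool)
    # paint tubuli first so glomeruli/arteries win any residual overlap
    for label in (ClassLabel.tubuli, ClassLabel.arteries, ClassLabel.glomeruli):
        for inst in instances:
            if inst.class_label is label:
                inst.paint(raster, int(label))
                inst.paint(structure_union, True)
    raster[~roi_mask] = int(ClassLabel.background)
    structure_union &= roi_mask

    stroma = region & ~structure_union
    if structure_union.any():
        w_px = microns_to_pixels(config.proper_stroma_width_um, calibration)
        dist = ndimage.distance_transform_edt(~structure_union)
        proper = (dist <= w_px) & stroma
    else:
        proper = np.zeros_like(stroma)
    raster[stroma] = int(ClassLabel.stroma)
    raster[proper] = int(ClassLabel.proper_stroma)
    return LabelMap(raster, calibration)
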