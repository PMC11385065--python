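"""Nucleus/lymphocyte detection and interstitial-infiltration mapping.

Cells are searched only in the stromal compartment. Candidate objects are
dark pixels under a grayscale threshold, split with a watershed on the
distance transform, and classified by fitted-ellipse shape, mean gray
brightness and size: lymphocytes are small, dark (mean gray < 95) and
near-round (semi-axis ratio < 2); everything else in the nucleus size gate
is a generic nucleus. Infiltration is mapped on a fixed 50 µm grid: a tile
is infiltrated when it holds at least 2 lymphocytes and at least 20
detected nuclei in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .config import CalibrationError, PipelineConfig, microns_to_pixels
from .labels import ClassLabel, LabelMap
from .masks import area_fraction
from .pipeline import to_grayscale

__all__ = [
    "CellObject",
    "MorphometryReport",
    "detect_cells",
    "tile_is_infiltrated",
    "map_infiltration",
    "compute_morphometry",
]


@dataclass(frozen=True)
class CellObject:
    """One detected nucleus or lymphocyte.

    Coordinates and lengths are physical (µm); brightness is mean gray
    (0-255) over the object's pixels.
    """

    centroid_um: tuple[float, float]  # (x, y)
    semi_axis_major_um: float
    semi_axis_minor_um: float
    mean_brightness: float
    area_um2: float
    cell_type: Literal["lymphocyte", "nucleus"]

    @property
    def axis_ratio(self) -> float:
        if self.semi_axis_minor_um == 0:
            return float("inf")
        return self.semi_axis_major_um / self.semi_axis_minor_um


@dataclass
class MorphometryReport:
    """Per-ROI relative areas and cell counts."""

    roi_id: str
    tissue_area_um2: float
    fibrosis_rel_area_pct: float
    infiltration_rel_area_pct: float
    n_lymphocytes: int
    n_nuclei: int
    n_infiltration_tiles: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


def _classify(
    axis_ratio: float, brightness: float, area_um2: float, config: PipelineConfig
) -> str | None:
    lo_l, hi_l = config.lymphocyte_area_range_um2
    lo_n, hi_n = config.nucleus_area_range_um2
    if (
        axis_ratio < config.lymphocyte_axis_ratio_max
        and brightness < config.lymphocyte_brightness_max
        and lo_l <= area_um2 <= hi_l
    ):
        return "lymphocyte"
    if lo_n <= area_um2 <= hi_n:
        return "nucleus"
    return None


def detect_cells(
    rgb: np.ndarray, label_map: LabelMap, config: PipelineConfig
) -> list[CellObject]:
    """Detect and classify cells inside the stromal compartment.

    Thresholding picks dark candidate objects, a watershed on the distance
    transform separates touching cells, and a moment-based ellipse is fitted
    to each object for the shape criterion.
    """
    calib = label_map.calibration
    if calib is None:
        raise CalibrationError("label map carries no calibration")
    px = calib.pixel_size_um
    if config.include_proper_stroma_in_cell_search:
        search = label_map.mask(
            ClassLabel.stroma, ClassLabel.proper_stroma, ClassLabel.infiltration
        )
    else:
        search = label_map.mask(ClassLabel.stroma, ClassLabel.infiltration)
    if not search.any():
        return []
    gray = to_grayscale(rgb)

    thr = config.cell_threshold
    if isinstance(thr, str):  # "otsu" within the stromal compartment
        values = gray[search]
        thr = config.cell_threshold_cap
        if np.ptp(values) > 0:
            thr = min(float(threshold_otsu(values)), config.cell_threshold_cap)
    candidates = (gray < float(thr)) & search
    if not candidates.any():
        return []

    # split touching cells: watershed on the distance transform
    dist = ndimage.distance_transform_edt(candidates)
    min_sep = max(2, microns_to_pixels(3.0, calib))
    peaks = peak_local_max(
        dist, min_distance=min_sep, labels=candidates, exclude_border=False
    )
    markers = np.zeros(candidates.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=candidates)

    cells: list[CellObject] = []
    for prop in regionprops(labels, intensity_image=gray):
        area_um2 = prop.area * px**2
        semi_major = prop.axis_major_length / 2.0 * px
        semi_minor = prop.axis_minor_length / 2.0 * px
        ratio = semi_major / semi_minor if semi_minor > 0 else float("inf")
        kind = _classify(ratio, float(prop.intensity_mean), area_um2, config)
        if kind is None:
            continue
        cy, cx = prop.centroid
        cells.append(
            CellObject(
                centroid_um=(cx * px, cy * px),
                semi_axis_major_um=semi_major,
                semi_axis_minor_um=semi_minor,
                mean_brightness=float(prop.intensity_mean),
                area_um2=area_um2,
                cell_type=kind,
            )
        )
    return cells


def tile_is_infiltrated(
    n_lymphocytes: int, n_other_nuclei: int, config: PipelineConfig | None = None
) -> bool:
    """The infiltration rule for one 50x50 µm tile.

    True iff the tile holds at least ``infiltration_min_lymphocytes`` (2)
    lymphocytes and at least ``infiltration_min_nuclei`` (20) nuclei. By
    default lymphocyte nuclei count toward the nucleus total (a lymphocyte
    is counted by its nucleus); the strict reading — 20 non-lymphocyte
    nuclei — is available via ``count_lymphocytes_as_nuclei=False``.
    """
    config = config or PipelineConfig()
    total = n_other_nuclei + (
        n_lymphocytes if config.count_lymphocytes_as_nuclei else 0
    )
    return (
        n_lymphocytes >= config.infiltration_min_lymphocytes
        and total >= config.infiltration_min_nuclei
    )


def map_infiltration(
    cells: Sequence[CellObject],
    label_map: LabelMap,
    config: PipelineConfig,
    roi_bounds_px: tuple[int, int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Flag infiltrated 50 µm tiles and paint the infiltration class.

    The tile grid is fixed (non-sliding) and anchored at the ROI
    bounding-box origin. The infiltration mask is the union of flagged
    tiles intersected with the fibrosis-eligible stroma (the proper stromal
    rim is excluded). ``label_map`` is updated in place.

    Returns ``(infiltration_mask, tile_flags, n_flagged)`` where
    ``tile_flags`` is the boolean grid of flagged tiles.
    """
    calib = label_map.calibration
    h, w = label_map.shape
    if roi_bounds_px is None:
        roi_bounds_px = (0, 0, w, h)
    bx0, by0, bx1, by1 = roi_bounds_px
    t = microns_to_pixels(config.infiltration_tile_um, calib)
    n_ty = max(1, -(-(by1 - by0) // t))
    n_tx = max(1, -(-(bx1 - bx0) // t))

    lymph = np.zeros((n_ty, n_tx), dtype=int)
    other = np.zeros((n_ty, n_tx), dtype=int)
    px = calib.pixel_size_um
    for cell in cells:
        cx, cy = cell.centroid_um
        tx = int((cx / px - bx0) // t)
        ty = int((cy / px - by0) // t)
        if 0 <= tx < n_tx and 0 <= ty < n_ty:
            if cell.cell_type == "lymphocyte":
                lymph[ty, tx] += 1
            else:
                other[ty, tx] += 1

    total = other + (lymph if config.count_lymphocytes_as_nuclei else 0)
    flags = (lymph >= config.infiltration_min_lymphocytes) & (
        total >= config.infiltration_min_nuclei
    )

    tiles_mask = np.zeros((h, w), dtype=bool)
    for ty, tx in zip(*np.nonzero(flags)):
        y0 = by0 + ty * t
        x0 = bx0 + tx * t
        tiles_mask[max(y0, 0) : min(y0 + t, h), max(x0, 0) : min(x0 + t, w)] = True
    infiltration = tiles_mask & label_map.mask(ClassLabel.stroma)
    label_map.raster[infiltration] = int(ClassLabel.infiltration)
    return infiltration, flags, int(flags.sum())


def compute_morphometry(
    label_map: LabelMap,
    roi_id: str = "roi",
    cells: Sequence[CellObject] = (),
    n_infiltration_tiles: int = 0,
) -> MorphometryReport:
    """Relative fibrosis and infiltration areas for a completed label map.

    Tissue is every non-background ROI pixel. Fibrosis is the stroma beyond
    the proper stromal rim (which, after infiltration mapping, is the union
    of the stroma and infiltration classes), infiltration the infiltration
    class; both relative to tissue, in percent.
    """
    tissue = label_map.raster != int(ClassLabel.background)
    if not tissue.any():
        raise ZeroDivisionError("label map contains no tissue")
    infiltration = label_map.mask(ClassLabel.infiltration)
    fibrosis = label_map.mask(ClassLabel.stroma) | infiltration
    return MorphometryReport(
        roi_id=roi_id,
        tissue_area_um2=label_map.calibration.area_px_to_um2(int(tissue.sum())),
        fibrosis_rel_area_pct=area_fraction(fibrosis, tissue),
        infiltration_rel_area_pct=area_fraction(infiltration, tissue),
        n_lymphocytes=sum(1 for c in cells if c.cell_type == "lymphocyte"),
        n_nuclei=sum(1 for c in cells if c.cell_type == "nucleus"),
        n_infiltration_tiles=n_infiltration_tiles,
    )
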