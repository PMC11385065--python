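"""Pixel calibration and pipeline configuration.

Every physical length in the pipeline is expressed in micrometers and
converted to pixels in exactly one place, :func:`microns_to_pixels`, so that
the same configuration behaves identically on slides scanned at different
magnifications (e.g. x20 at 0.5056 µm/px, x40 at 0.2519 µm/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = [
    "PixelCalibration",
    "PipelineConfig",
    "CalibrationError",
    "ConfigError",
    "microns_to_pixels",
    "X20_CALIBRATION",
    "X40_CALIBRATION",
]


class CalibrationError(ValueError):
    """Raised for invalid physical calibration (non-positive pixel size)."""


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration content."""


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of one pixel.

    Parameters
    ----------
    pixel_size_um : float
        Edge length of one pixel in micrometers; must be positive.
    magnification_label : str
        Free-text tag such as ``"x20"`` or ``"x40"``; informational only.
    """

    pixel_size_um: float
    magnification_label: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise CalibrationError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um!r}"
            )

    def to_pixels(self, length_um: float) -> int:
        return microns_to_pixels(length_um, self)

    def to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um

    def area_px_to_um2(self, area_px: float) -> float:
        return area_px * self.pixel_size_um**2


#: Scanner calibrations of the two magnifications the pipeline targets.
X20_CALIBRATION = PixelCalibration(0.5056, "x20")
X40_CALIBRATION = PixelCalibration(0.2519, "x40")


def microns_to_pixels(length_um: float, calib: PixelCalibration) -> int:
    """Convert a physical length to a whole pixel count.

    Rounding is half-away-from-zero, so a 50 µm window at x20
    (0.5056 µm/px, 50/0.5056 = 98.89) yields 99 pixels.

    Parameters
    ----------
    length_um : float
        Nonnegative length in micrometers.
    calib : PixelCalibration
        Pixel size to convert with.
    """
    if length_um < 0:
        raise ValueError(f"length_um must be >= 0, got {length_um}")
    if not (calib.pixel_size_um > 0):
        raise CalibrationError("non-positive pixel size")
    # round-half-away-from-zero (length is nonnegative here)
    return int(math.floor(length_um / calib.pixel_size_um + 0.5))


def _diameter_range_to_area_range(d_lo: float, d_hi: float) -> tuple[float, float]:
    """Equivalent-diameter range (µm) -> area range (µm²) of the same disks."""
    return (math.pi / 4.0 * d_lo**2, math.pi / 4.0 * d_hi**2)


@dataclass
class PipelineConfig:
    """All numeric constants of the morphometry pipeline.

    Lengths are micrometers, areas µm², brightness on the 8-bit gray scale.

    Attributes
    ----------
    window_um : float
        Sliding-window edge for segmentation (50 µm; 99 px at x20).
    proper_stroma_width_um : float
        Width of the normal ("proper") stromal rim around each tissue
        structure, excluded from fibrosis accounting. The physiologic rim is
        15–20 µm wide; default 15.
    lymphocyte_axis_ratio_max : float
        Lymphocytes are near-round: ellipse semi-axis ratio must be < 2.
    lymphocyte_brightness_max : float
        Lymphocyte nuclei are dark: mean gray value must be < 95 (0–255).
    infiltration_tile_um : float
        Edge of the fixed grid tiles used for the infiltration rule (50 µm).
    infiltration_min_lymphocytes : int
        A tile is infiltrated when it holds at least this many lymphocytes...
    infiltration_min_nuclei : int
        ...and at least this many detected cells in total (default 20).
    count_lymphocytes_as_nuclei : bool
        If True (default) the "20 nuclei" count includes lymphocyte nuclei;
        if False only non-lymphocyte nuclei count toward it.
    merge_iou_min : float
        Strong-intersection threshold for merging same-class instances
        (intersection over minimum area), in (0, 1].
    border_discard_area_um2 : float
        Instances touching a sliding-window border smaller than this are
        discarded as unstable fragments.
    tissue_threshold : float | str
        Grayscale cutoff below which a pixel is tissue, or ``"otsu"``.
    lymphocyte_area_range_um2, nucleus_area_range_um2 : (float, float)
        Size gates for cell classification, derived from equivalent
        diameters of 4–10 µm (lymphocytes) and 4–15 µm (any nucleus).
    cell_threshold : float | str
        Candidate-cell grayscale cutoff inside stroma; ``"otsu"`` computes
        Otsu within the stromal compartment, capped at ``cell_threshold_cap``.
    include_proper_stroma_in_cell_search : bool
        Whether nuclei/lymphocytes are also searched in the proper stromal
        rim (default True).
    """

    window_um: float = 50.0
    proper_stroma_width_um: float = 15.0
    lymphocyte_axis_ratio_max: float = 2.0
    lymphocyte_brightness_max: float = 95.0
    infiltration_tile_um: float = 50.0
    infiltration_min_lymphocytes: int = 2
    infiltration_min_nuclei: int = 20
    count_lymphocytes_as_nuclei: bool = True
    merge_iou_min: float = 0.5
    border_discard_area_um2: float = 100.0
    tissue_threshold: float | str = 230.0
    lymphocyte_area_range_um2: tuple[float, float] = field(
        default_factory=lambda: _diameter_range_to_area_range(4.0, 10.0)
    )
    nucleus_area_range_um2: tuple[float, float] = field(
        default_factory=lambda: _diameter_range_to_area_range(4.0, 15.0)
    )
    cell_threshold: float | str = "otsu"
    cell_threshold_cap: float = 180.0
    include_proper_stroma_in_cell_search: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            ("window_um", self.window_um),
            ("proper_stroma_width_um", self.proper_stroma_width_um),
            ("lymphocyte_axis_ratio_max", self.lymphocyte_axis_ratio_max),
            ("lymphocyte_brightness_max", self.lymphocyte_brightness_max),
            ("infiltration_tile_um", self.infiltration_tile_um),
            ("border_discard_area_um2", self.border_discard_area_um2),
            ("cell_threshold_cap", self.cell_threshold_cap),
        ]
        for name, value in positive:
            if not (value > 0):
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.infiltration_min_lymphocytes < 0 or self.infiltration_min_nuclei < 0:
            raise ConfigError("infiltration count thresholds must be >= 0")
        if not (0 < self.merge_iou_min <= 1):
            raise ConfigError(
                f"merge_iou_min must be in (0, 1], got {self.merge_iou_min}"
            )
        for name in ("tissue_threshold", "cell_threshold"):
            value = getattr(self, name)
            if isinstance(value, str):
                if value != "otsu":
                    raise ConfigError(f"{name} must be a number or 'otsu'")
            elif not (0 < float(value) <= 255):
                raise ConfigError(f"{name} must be in (0, 255]")
        for name in ("lymphocyte_area_range_um2", "nucleus_area_range_um2"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must be an increasing positive range")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lymphocyte_area_range_um2"] = list(self.lymphocyte_area_range_um2)
        d["nucleus_area_range_um2"] = list(self.nucleus_area_range_um2)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for name in ("lymphocyte_area_range_um2", "nucleus_area_range_um2"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)
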