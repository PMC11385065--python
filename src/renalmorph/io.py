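"""File formats and the end-to-end pipeline runner.

Annotations travel as QuPath-style GeoJSON FeatureCollections: each feature
carries a Polygon/MultiPolygon geometry in pixel coordinates and a
``classification.name`` property from the closed label set; the pixel
calibration rides in a top-level ``calibration`` sidecar field. Label maps
are written as single-channel palette PNGs whose integer values are the
``ClassLabel`` codes. Reports append rows to a documented CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import MultiPolygon, Polygon, shape as shapely_shape

from .cells import MorphometryReport, compute_morphometry, detect_cells, map_infiltration
from .config import PipelineConfig, PixelCalibration
from .geometry import RoiPolygon, mask_to_polygon, rasterize_polygon
from .labels import ClassLabel, LabelMap, OVERLAY_PALETTE, STRUCTURE_CLASSES
from .masks import InstanceMask
from .pipeline import Segmenter, derive_stroma, detect_tissue, merge_instances, scan_slide

__all__ = [
    "read_image",
    "write_image",
    "write_label_map_png",
    "read_label_map_png",
    "write_annotations",
    "read_annotations",
    "write_overlay",
    "append_report_csv",
    "run_full_pipeline",
]

logger = logging.getLogger("renalmorph")

REPORT_CSV_FIELDS = [
    "roi_id",
    "tissue_area_um2",
    "fibrosis_rel_area_pct",
    "infiltration_rel_area_pct",
    "n_lymphocytes",
    "n_nuclei",
    "n_infiltration_tiles",
]


# -- images ----------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        Image.fromarray(rgb).save(path)


def write_label_map_png(path: str | Path, label_map: LabelMap) -> None:
    """Single-channel PNG; pixel values are ClassLabel codes (documented)."""
    img = Image.fromarray(label_map.raster, mode="L")
    palette = []
    for code in range(256):
        try:
            palette.extend(OVERLAY_PALETTE[ClassLabel(code)])
        except ValueError:
            palette.extend((0, 0, 0))
    img = img.convert("P")
    img.putpalette(palette)
    img.save(path)


def read_label_map_png(path: str | Path, calibration: PixelCalibration) -> LabelMap:
    raster = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    return LabelMap(raster, calibration)


def write_overlay(path: str | Path, rgb: np.ndarray, label_map: LabelMap, alpha: float = 0.45) -> None:
    """Semi-transparent class overlay in the standard palette."""
    colored = label_map.to_rgb().astype(float)
    fg = label_map.raster != int(ClassLabel.background)
    out = rgb.astype(float).copy()
    out[fg] = (1 - alpha) * out[fg] + alpha * colored[fg]
    write_image(path, out.astype(np.uint8))


# -- GeoJSON annotations ---------------------------------------------------


def _geometry_to_json(geom: Polygon | MultiPolygon) -> dict:
    from shapely.geometry import mapping

    return mapping(geom)


def write_annotations(
    path: str | Path,
    instances: list[InstanceMask] = (),
    rois: list[RoiPolygon] = (),
    calibration: PixelCalibration | None = None,
) -> None:
    """Write instances and ROI polygons as a GeoJSON FeatureCollection."""
    features = []
    for inst in instances:
        x0, y0, _, _ = inst.bbox
        geom = mask_to_polygon(inst.mask, origin=(x0, y0))
        features.append(
            {
                "type": "Feature",
                "geometry": _geometry_to_json(geom),
                "properties": {
                    "classification": {"name": inst.class_label.name},
                    "score": inst.score,
                    "objectType": "annotation",
                },
            }
        )
    for roi in rois:
        features.append(
            {
                "type": "Feature",
                "geometry": _geometry_to_json(roi.polygon),
                "properties": {
                    "classification": {"name": roi.label},
                    "objectType": "roi",
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if calibration is not None:
        doc["calibration"] = {
            "pixel_size_um": calibration.pixel_size_um,
            "magnification_label": calibration.magnification_label,
        }
    Path(path).write_text(json.dumps(doc))


class AnnotationParseError(ValueError):
    pass


def read_annotations(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> tuple[list[InstanceMask], list[RoiPolygon], PixelCalibration | None]:
    """Read a GeoJSON FeatureCollection back into instances and ROIs.

    Structure-class features are rasterized (pixel-center rule, the exact
    inverse of the writer); features with unknown class names are rejected
    with a listing. Round trip write -> read is lossless.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise AnnotationParseError("not a GeoJSON FeatureCollection")
    calib = None
    if "calibration" in doc:
        calib = PixelCalibration(**doc["calibration"])
    structure_names = {c.name for c in STRUCTURE_CLASSES}
    known_names = {c.name for c in ClassLabel}
    instances: list[InstanceMask] = []
    rois: list[RoiPolygon] = []
    unknown: list[str] = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shapely_shape(feat["geometry"])
        except Exception as exc:
            raise AnnotationParseError(f"feature {i}: invalid geometry ({exc})") from exc
        if not geom.is_valid:
            raise AnnotationParseError(f"feature {i}: invalid geometry")
        props = feat.get("properties", {})
        name = (props.get("classification") or {}).get("name", "")
        if props.get("objectType") == "roi" or name not in known_names:
            if props.get("objectType") == "roi":
                rois.append(RoiPolygon(geom, name or "roi"))
                continue
            unknown.append(name)
            continue
        if name not in structure_names:
            unknown.append(name)
            continue
        minx, miny, maxx, maxy = geom.bounds
        x0, y0 = int(np.floor(minx)), int(np.floor(miny))
        x1, y1 = int(np.ceil(maxx)), int(np.ceil(maxy))
        mask = rasterize_polygon(geom, (y1 - y0, x1 - x0), origin=(x0, y0))
        if not mask.any():
            raise AnnotationParseError(f"feature {i}: rasterizes to an empty mask")
        instances.append(
            InstanceMask.from_full_mask(
                ClassLabel[name], mask, float(props.get("score", 1.0)), origin=(x0, y0)
            )
        )
    if unknown:
        raise AnnotationParseError(f"unknown class names: {sorted(set(unknown))}")
    return instances, rois, calib


# -- CSV reports -----------------------------------------------------------


def append_report_csv(path: str | Path, report: MorphometryReport) -> None:
    path = Path(path)
    row = report.to_row()
    if set(row) != set(REPORT_CSV_FIELDS):
        raise ValueError("report row does not match the documented schema")
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_CSV_FIELDS)
        if new:
            writer.writeheader()
        writer.writerow(row)


# -- end to end ------------------------------------------------------------


def run_full_pipeline(
    image: np.ndarray | str | Path,
    segmenter: Segmenter,
    calibration: PixelCalibration,
    config: PipelineConfig | None = None,
    roi: RoiPolygon | None = None,
    roi_id: str = "roi",
    out_dir: str | Path | None = None,
) -> tuple[MorphometryReport, LabelMap]:
    """Tissue detection -> scan -> merge -> stroma -> cells -> infiltration.

    When ``out_dir`` is given, writes the label-map PNG, a palette overlay
    PNG, the merged instances as GeoJSON and appends the report row to
    ``reports.csv`` there. Stage timings and counts are logged.
    """
    config = config or PipelineConfig()
    rgb = read_image(image) if isinstance(image, (str, Path)) else np.asarray(image)

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        logger.info("%s: %.2fs", name, time.perf_counter() - t0)
        return result

    tissue = stage("detect_tissue", lambda: detect_tissue(rgb, config.tissue_threshold))
    raw = stage(
        "scan_slide", lambda: scan_slide(rgb, tissue, segmenter, config, calibration)
    )
    merged = stage(
        "merge_instances", lambda: merge_instances(raw, config.merge_iou_min)
    )
    logger.info("instances: %d raw -> %d merged", len(raw), len(merged))
    label_map = stage(
        "derive_stroma", lambda: derive_stroma(tissue, merged, roi, config, calibration)
    )
    cells = stage("detect_cells", lambda: detect_cells(rgb, label_map, config))
    if roi is None:
        bounds = None
    else:
        minx, miny, maxx, maxy = roi.polygon.bounds
        bounds = (int(minx), int(miny), int(np.ceil(maxx)), int(np.ceil(maxy)))
    _, _, n_tiles = stage(
        "map_infiltration", lambda: map_infiltration(cells, label_map, config, bounds)
    )
    report = compute_morphometry(label_map, roi_id, cells, n_tiles)
    logger.info(
        "%s: fibrosis %.2f%%, infiltration %.2f%% (%d lymphocytes, %d nuclei)",
        roi_id,
        report.fibrosis_rel_area_pct,
        report.infiltration_rel_area_pct,
        report.n_lymphocytes,
        report.n_nuclei,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_label_map_png(out_dir / f"{roi_id}_labels.png", label_map)
        write_overlay(out_dir / f"{roi_id}_overlay.png", rgb, label_map)
        write_annotations(
            out_dir / f"{roi_id}_instances.geojson", merged, calibration=calibration
        )
        append_report_csv(out_dir / "reports.csv", report)
    return report, label_map
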