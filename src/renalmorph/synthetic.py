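"""Synthetic H&E-like renal cortex with exhaustive ground truth.

The generator emulates the geometry of renal cortex at the level the
morphometry pipeline cares about, not photorealistic staining:

* glomeruli — oval structures 100-150 µm across, including the Bowman
  capsule in their true borders;
* tubules — a densely packed Voronoi collection of polygonal structures,
  30-50 µm;
* arteries — round, >= 100 µm, with wall and lumen;
* stroma — the connective-tissue space between structures. Fibrosis is
  emulated by replacing clusters of tubules with stroma (as connective
  tissue replaces parenchyma), grown until the fibrosis-eligible stroma
  (beyond the 15 µm proper rim) reaches the requested fraction of tissue;
* infiltration — 50 µm grid-aligned clusters of stroma densely populated
  with lymphocytes (dark, near-round) among ordinary nuclei (lighter,
  more elongated);
* background — near-white, so grayscale thresholding separates tissue.

Every slide ships with its ground-truth label map, instance list, cell
list and true fibrosis/infiltration percentages computed by the same area
definitions the pipeline uses, so parameter recovery is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk, erosion

from .cells import CellObject, compute_morphometry
from .config import PipelineConfig, PixelCalibration, X20_CALIBRATION, microns_to_pixels
from .labels import ClassLabel, LabelMap
from .masks import InstanceMask
from .pipeline import derive_stroma

__all__ = [
    "SynthParams",
    "SynthSlide",
    "InfeasibleTargetsError",
    "generate_slide",
    "oracle_segmenter",
    "make_oracle_segmenter",
    "corrupt_segmentation",
]

# luminance weights matching skimage.color.rgb2gray
_LUM = np.array([0.2125, 0.7154, 0.0721])


class InfeasibleTargetsError(ValueError):
    """Requested fibrosis/infiltration targets cannot fit the slide."""


@dataclass
class SynthParams:
    """Stated world of the generator.

    Densities are counts per 50x50 µm tile. Class area ratio is the target
    tubuli:glomeruli:arteries pixel-volume ratio (40:3:2 in normal cortex).
    Default fibrosis/infiltration targets correspond to a mildly fibrotic
    slide (ci around 1).
    """

    image_size_px: int = 1280
    calibration: PixelCalibration = X20_CALIBRATION
    seed: int = 0
    class_area_ratio: tuple[float, float, float] = (40.0, 3.0, 2.0)
    glomerulus_diameter_um_range: tuple[float, float] = (100.0, 150.0)
    tubule_size_um_range: tuple[float, float] = (30.0, 50.0)
    artery_diameter_um_min: float = 100.0
    fibrosis_fraction_target: float = 0.24
    infiltration_fraction_target: float = 0.06
    lymphocyte_density_in_infiltrate: int = 12
    nucleus_density_in_infiltrate: int = 12
    nucleus_density: float = 4.0
    lymphocyte_density: float = 0.2
    intertubule_gap_um: float = 10.0
    border_margin_um: float = 12.0
    noise_sigma: float = 0.0
    strict_targets: bool = True  # raise when a target cannot be realized
    pipeline_config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.image_size_px < 256:
            raise ValueError("image_size_px must be >= 256")
        if not (0 <= self.fibrosis_fraction_target <= 0.8):
            raise ValueError("fibrosis_fraction_target must be in [0, 0.8]")
        if not (0 <= self.infiltration_fraction_target <= 0.6):
            raise ValueError("infiltration_fraction_target must be in [0, 0.6]")
        for name in ("glomerulus_diameter_um_range", "tubule_size_um_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive range")


# rendering palette: all tissue luminances sit well below the 230 tissue
# threshold; stroma (214) sits above the 180 cell-threshold cap, cells below
_COLORS = {
    "background": (248, 248, 248),
    "stroma": (243, 205, 215),
    "tubule": (226, 160, 180),
    "glom_tuft": (190, 140, 160),
    "bowman_space": (236, 222, 228),
    "capsule": (170, 130, 150),
    "artery_wall": (200, 140, 150),
    "artery_lumen": (235, 215, 220),
}


@dataclass
class SynthSlide:
    """A generated slide with its complete ground truth."""

    rgb_image: np.ndarray
    ground_truth: LabelMap
    instances: list[InstanceMask]
    cells: list[CellObject]
    true_fibrosis_pct: float
    true_infiltration_pct: float
    params: SynthParams


def _tinted_gray(v: float) -> tuple[int, int, int]:
    """A bluish-purple nuclear color whose rgb2gray luminance equals v."""
    b = min(255.0, v + 25.0)
    g = v
    r = (v - _LUM[1] * g - _LUM[2] * b) / _LUM[0]
    r = min(255.0, max(0.0, r))
    return (int(round(r)), int(round(g)), int(round(b)))


def _jittered_grid(rng, lo: int, hi: int, spacing: float) -> np.ndarray:
    """Jittered square grid of (y, x) points covering [lo, hi)^2."""
    ax = np.arange(lo + spacing / 2, hi, spacing)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    pts += rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    return np.clip(pts, lo, hi - 1)


def _fibrosis_pct(
    tissue: np.ndarray, structures: np.ndarray, rim_px: int
) -> tuple[float, np.ndarray]:
    stroma = tissue & ~structures
    if structures.any():
        dist = ndimage.distance_transform_edt(~structures)
        eligible = stroma & (dist > rim_px)
    else:
        eligible = stroma
    return 100.0 * eligible.sum() / tissue.sum(), eligible


def _place_round_structures(
    rng,
    n: int,
    diam_px_range: tuple[float, float],
    occupied: np.ndarray,
    tissue_lo: int,
    tissue_hi: int,
    clearance_px: float,
    axis_ratio_max: float = 1.25,
    tries: int = 200,
) -> list[tuple[float, float, float, float, float]]:
    """Sample (cy, cx, a, b, theta) ellipses that avoid ``occupied``."""
    out = []
    for _ in range(n):
        for _attempt in range(tries):
            d = rng.uniform(*diam_px_range)
            ratio = rng.uniform(1.0, axis_ratio_max)
            a = d / 2.0 * np.sqrt(ratio)  # semi-major
            b = d / 2.0 / np.sqrt(ratio)
            theta = rng.uniform(0, np.pi)
            m = a + clearance_px
            cy = rng.uniform(tissue_lo + m, tissue_hi - m)
            cx = rng.uniform(tissue_lo + m, tissue_hi - m)
            rr, cc = draw_ellipse(cy, cx, a + clearance_px, b + clearance_px,
                                  rotation=theta, shape=occupied.shape)
            if not occupied[rr, cc].any():
                out.append((cy, cx, a, b, theta))
                rr, cc = draw_ellipse(cy, cx, a + clearance_px, b + clearance_px,
                                      rotation=theta, shape=occupied.shape)
                occupied[rr, cc] = True
                break
    return out


def _build_geometry(params: SynthParams, glom_scale: float, artery_scale: float, ss):
    """One geometry pass; scales adjust glomerulus/artery diameters."""
    n = params.image_size_px
    calib = params.calibration
    um = lambda v: v / calib.pixel_size_um  # µm -> px (float)
    rng_glom = np.random.default_rng(ss[0])
    rng_tub = np.random.default_rng(ss[1])
    rng_fib = np.random.default_rng(ss[2])

    margin = microns_to_pixels(params.border_margin_um, calib)
    tissue = np.zeros((n, n), dtype=bool)
    tissue[margin : n - margin, margin : n - margin] = True
    tissue_area = tissue.sum()
    gap_px = um(params.intertubule_gap_um)
    rim_px = microns_to_pixels(params.pipeline_config.proper_stroma_width_um, calib)

    # --- budget: how much structure area the targets leave room for
    r_t, r_g, r_a = params.class_area_ratio
    total_ratio = r_t + r_g + r_a
    packed_fill = 0.64  # tubule fill fraction of a packed region (gap overhead)
    struct_budget = tissue_area * (1.0 - params.fibrosis_fraction_target) * 0.68

    glom_lo, glom_hi = (um(v) for v in params.glomerulus_diameter_um_range)
    target_glom = struct_budget * r_g / total_ratio
    mean_glom_area = np.pi / 4.0 * ((glom_lo + glom_hi) / 2.0) ** 2
    n_glom = max(1, int(round(target_glom / mean_glom_area)))
    d_mean = np.sqrt(4.0 * target_glom / n_glom / np.pi) * glom_scale
    d_lo = np.clip(d_mean * 0.92, glom_lo, glom_hi)
    d_hi = np.clip(d_mean * 1.08, glom_lo, glom_hi)

    art_lo = um(params.artery_diameter_um_min)
    target_art = struct_budget * r_a / total_ratio
    n_art = max(1, int(round(target_art / (np.pi / 4.0 * (art_lo * 1.1) ** 2))))
    da = np.sqrt(4.0 * target_art / n_art / np.pi) * artery_scale
    da = max(da, art_lo)

    occupied = np.zeros((n, n), dtype=bool)
    gloms = _place_round_structures(
        rng_glom, n_glom, (d_lo, d_hi), occupied, margin, n - margin, gap_px
    )
    arteries = _place_round_structures(
        rng_glom, n_art, (da * 0.95, da * 1.05), occupied, margin, n - margin,
        gap_px, axis_ratio_max=1.05,
    )

    big_union = np.zeros((n, n), dtype=bool)
    glom_shapes, art_shapes = [], []
    for cy, cx, a, b, th in gloms:
        m = np.zeros((n, n), dtype=bool)
        rr, cc = draw_ellipse(cy, cx, a, b, rotation=th, shape=(n, n))
        m[rr, cc] = True
        glom_shapes.append((m, (cy, cx, a, b, th)))
        big_union |= m
    for cy, cx, a, b, th in arteries:
        m = np.zeros((n, n), dtype=bool)
        rr, cc = draw_ellipse(cy, cx, a, b, rotation=th, shape=(n, n))
        m[rr, cc] = True
        art_shapes.append((m, (cy, cx, a, b, th)))
        big_union |= m

    # --- tubule packing: shrunk Voronoi cells in the remaining tissue
    t_lo, t_hi = params.tubule_size_um_range
    spacing = um((t_lo + t_hi) / 2.0 + params.intertubule_gap_um)
    seeds = _jittered_grid(rng_tub, margin, n - margin, spacing)
    tree = cKDTree(seeds)
    ys, xs = np.nonzero(tissue)
    pix = np.stack([ys, xs], axis=1).astype(float)
    dists, idx = tree.query(pix, k=2, workers=-1)
    interior = (dists[:, 1] - dists[:, 0]) >= gap_px
    tub_label = np.zeros((n, n), dtype=np.int32)
    tub_label[ys[interior], xs[interior]] = idx[interior, 0] + 1
    # keep clear of glomeruli/arteries and their stromal gap
    if big_union.any():
        keepout = ndimage.distance_transform_edt(~big_union) <= gap_px
        tub_label[keepout] = 0
    # drop sliver fragments
    min_tub_px = um(np.sqrt(300.0)) ** 2  # 300 µm² in px²
    counts = np.bincount(tub_label.ravel())
    small = np.nonzero(counts < min_tub_px)[0]
    tub_label[np.isin(tub_label, small[small > 0])] = 0

    # --- fibrosis: replace clusters of tubules with stroma until the
    #     fibrosis-eligible compartment reaches the target
    present = sorted(set(np.unique(tub_label)) - {0})
    centers = {lab: seeds[lab - 1] for lab in present}
    structures = big_union | (tub_label > 0)
    target = 100.0 * params.fibrosis_fraction_target
    fib, eligible = _fibrosis_pct(tissue, structures, rim_px)
    dropped: set[int] = set()
    focus = None
    while fib < target - 1.0:
        remaining = [lab for lab in present if lab not in dropped]
        if not remaining:
            if not params.strict_targets:
                break
            raise InfeasibleTargetsError(
                f"fibrosis target {target:.0f}% unreachable: all tubules dropped "
                f"at {fib:.1f}%"
            )
        if focus is None or not remaining:
            focus = centers[remaining[rng_fib.integers(len(remaining))]]
        # drop the few remaining tubules nearest to the focus (patch growth)
        order = sorted(remaining, key=lambda lab: float(np.hypot(*(centers[lab] - focus))))
        chunk = order[: max(2, len(order) // 40)]
        for lab in chunk:
            dropped.add(lab)
            tub_label[tub_label == lab] = 0
        if rng_fib.random() < 0.15:
            focus = None  # start a new fibrotic focus now and then
        structures = big_union | (tub_label > 0)
        fib, eligible = _fibrosis_pct(tissue, structures, rim_px)

    return {
        "tissue": tissue,
        "glom_shapes": glom_shapes,
        "art_shapes": art_shapes,
        "tub_label": tub_label,
        "big_union": big_union,
        "fibrosis_pct": fib,
        "eligible": eligible,
        "rim_px": rim_px,
    }


def _instances_from_geometry(geo) -> list[InstanceMask]:
    out = []
    for m, _ in geo["glom_shapes"]:
        out.append(InstanceMask.from_full_mask(ClassLabel.glomeruli, m, 1.0))
    for m, _ in geo["art_shapes"]:
        out.append(InstanceMask.from_full_mask(ClassLabel.arteries, m, 1.0))
    tub = geo["tub_label"]
    for lab, sl in enumerate(ndimage.find_objects(tub), start=1):
        if sl is None:
            continue
        sub = tub[sl] == lab
        if not sub.any():
            continue
        out.append(
            InstanceMask.from_full_mask(
                ClassLabel.tubuli, sub, 1.0, origin=(sl[1].start, sl[0].start)
            )
        )
    return out


def generate_slide(params: SynthParams | None = None) -> SynthSlide:
    """Generate one synthetic renal-cortex slide with full ground truth.

    Deterministic: the same params (including seed) give byte-identical
    output. Raises :class:`InfeasibleTargetsError` when the fibrosis or
    infiltration target cannot be realized within 3 percentage points.
    """
    params = params or SynthParams()
    calib = params.calibration
    n = params.image_size_px
    cfg = params.pipeline_config
    seeds = np.random.SeedSequence(params.seed).spawn(6)

    # pass 1 with nominal sizes, pass 2 rescales glomeruli/arteries toward
    # the requested class-volume ratio using the realized tubule area
    geo = _build_geometry(params, 1.0, 1.0, seeds[:3])
    t_area = int((geo["tub_label"] > 0).sum())
    g_area = sum(int(m.sum()) for m, _ in geo["glom_shapes"])
    a_area = sum(int(m.sum()) for m, _ in geo["art_shapes"])
    r_t, r_g, r_a = params.class_area_ratio
    glom_scale = np.sqrt((t_area * r_g / r_t) / g_area) if g_area else 1.0
    art_scale = np.sqrt((t_area * r_a / r_t) / a_area) if a_area else 1.0
    geo = _build_geometry(
        params, float(np.clip(glom_scale, 0.6, 1.6)), float(np.clip(art_scale, 0.6, 1.6)),
        seeds[:3],
    )

    instances = _instances_from_geometry(geo)
    tissue = geo["tissue"]

    label_map = derive_stroma(tissue, instances, None, cfg, calib)

    # --- infiltration: pick 50 µm grid tiles rich in fibrosis-eligible
    #     stroma, cluster-grown until the target area is met
    rng_inf = np.random.default_rng(seeds[3])
    rng_cell = np.random.default_rng(seeds[4])
    t_px = microns_to_pixels(cfg.infiltration_tile_um, calib)
    stroma_cls = label_map.mask(ClassLabel.stroma)
    allowed = label_map.mask(ClassLabel.stroma, ClassLabel.proper_stroma)
    allowed_edt = ndimage.distance_transform_edt(allowed)
    n_tiles = -(-n // t_px)

    def tile_box(ty, tx):
        return (
            slice(ty * t_px, min((ty + 1) * t_px, n)),
            slice(tx * t_px, min((tx + 1) * t_px, n)),
        )

    eligible_in_tile = np.zeros((n_tiles, n_tiles))
    for ty in range(n_tiles):
        for tx in range(n_tiles):
            sly, slx = tile_box(ty, tx)
            eligible_in_tile[ty, tx] = stroma_cls[sly, slx].mean()

    candidates = {
        (ty, tx)
        for ty in range(n_tiles)
        for tx in range(n_tiles)
        if eligible_in_tile[ty, tx] >= 0.55
    }
    target_inf_px = params.infiltration_fraction_target * tissue.sum()
    chosen: list[tuple[int, int]] = []
    planned_cells: list[tuple[tuple[int, int], list]] = []
    inf_px = 0
    frontier: list[tuple[int, int]] = []
    while inf_px < target_inf_px and candidates:
        if frontier:
            ty, tx = frontier.pop()
        else:
            ty, tx = sorted(candidates)[rng_inf.integers(len(candidates))]
        if (ty, tx) not in candidates:
            continue
        candidates.discard((ty, tx))
        sly, slx = tile_box(ty, tx)
        planned = _plan_tile_cells(
            rng_cell, (sly, slx), params.lymphocyte_density_in_infiltrate,
            params.nucleus_density_in_infiltrate, allowed_edt, calib, params,
        )
        n_lymph = sum(1 for c, _ in planned if c.cell_type == "lymphocyte")
        # accept only when the tile satisfies the infiltration rule with a
        # margin, so detection losses cannot unflag it
        if not (
            n_lymph >= cfg.infiltration_min_lymphocytes + 1
            and len(planned) >= cfg.infiltration_min_nuclei + 2
        ):
            continue
        chosen.append((ty, tx))
        planned_cells.append(((ty, tx), planned))
        inf_px += int(stroma_cls[sly, slx].sum())
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (ty + dy, tx + dx) in candidates:
                frontier.append((ty + dy, tx + dx))
    realized_inf_pct = 100.0 * inf_px / tissue.sum()
    if params.strict_targets and (
        realized_inf_pct < 100.0 * params.infiltration_fraction_target - 3.0
    ):
        raise InfeasibleTargetsError(
            f"infiltration target {100 * params.infiltration_fraction_target:.0f}% "
            f"unreachable: only {realized_inf_pct:.1f}% of fibrosis-eligible stroma "
            "available"
        )

    # paint ground-truth infiltration
    chosen_set = set(chosen)
    for ty, tx in chosen:
        sly, slx = tile_box(ty, tx)
        region = label_map.raster[sly, slx]
        region[stroma_cls[sly, slx]] = int(ClassLabel.infiltration)

    # --- background nuclei in the remaining stroma
    all_planned: list[tuple[CellObject, float]] = []
    for _, planned in planned_cells:
        all_planned.extend(planned)
    for ty in range(n_tiles):
        for tx in range(n_tiles):
            if (ty, tx) in chosen_set:
                continue
            sly, slx = tile_box(ty, tx)
            frac = allowed[sly, slx].mean()
            if frac == 0:
                continue
            n_nuc = int(rng_cell.poisson(params.nucleus_density * frac))
            n_lym = int(rng_cell.poisson(params.lymphocyte_density * frac))
            if n_nuc + n_lym == 0:
                continue
            all_planned.extend(
                _plan_tile_cells(
                    rng_cell, (sly, slx), n_lym, n_nuc, allowed_edt, calib, params
                )
            )

    all_cells = [c for c, _ in all_planned]
    rgb = _render(params, geo, all_planned, rng_cell)

    truth_report = compute_morphometry(label_map, "ground_truth")
    return SynthSlide(
        rgb_image=rgb,
        ground_truth=label_map,
        instances=instances,
        cells=all_cells,
        true_fibrosis_pct=truth_report.fibrosis_rel_area_pct,
        true_infiltration_pct=truth_report.infiltration_rel_area_pct,
        params=params,
    )


def _plan_tile_cells(rng, tile, n_lymph, n_nuc, allowed_edt, calib, params):
    """Plan non-overlapping cells on a slot grid inside one tile.

    Lymphocytes: near-circular disks, mean gray 50-90 (< 95 by
    construction). Nuclei: ellipses with axis ratio up to ~2.2, gray
    100-160 (>= 95). Cells are only placed where they fit entirely inside
    the stromal compartment.
    """
    px = calib.pixel_size_um
    sly, slx = tile
    h, w = sly.stop - sly.start, slx.stop - slx.start
    n_slots = 7
    step_y, step_x = h / n_slots, w / n_slots
    slots = [(i, j) for i in range(n_slots) for j in range(n_slots)]
    rng.shuffle(slots)
    kinds = ["lymphocyte"] * n_lymph + ["nucleus"] * n_nuc
    cells: list[tuple[CellObject, float]] = []
    for kind in kinds:
        while slots:
            i, j = slots.pop()
            cy = sly.start + (i + 0.5) * step_y + rng.uniform(-0.15, 0.15) * step_y
            cx = slx.start + (j + 0.5) * step_x + rng.uniform(-0.15, 0.15) * step_x
            if kind == "lymphocyte":
                d_um = rng.uniform(5.0, 7.5)
                ratio = rng.uniform(1.0, 1.15)
                gray = rng.uniform(50.0, 90.0)
            else:
                d_um = rng.uniform(5.5, 7.5)
                ratio = rng.uniform(1.3, 2.2)
                gray = rng.uniform(100.0, 160.0)
            a_um = d_um / 2.0 * np.sqrt(ratio)
            b_um = d_um / 2.0 / np.sqrt(ratio)
            theta = rng.uniform(0, np.pi)
            iy, ix = int(round(cy)), int(round(cx))
            if not (0 <= iy < allowed_edt.shape[0] and 0 <= ix < allowed_edt.shape[1]):
                continue
            if allowed_edt[iy, ix] <= a_um / px + 1:
                continue
            cells.append(
                (
                    CellObject(
                        centroid_um=(cx * px, cy * px),
                        semi_axis_major_um=a_um,
                        semi_axis_minor_um=b_um,
                        mean_brightness=gray,
                        area_um2=np.pi * a_um * b_um,
                        cell_type=kind,
                    ),
                    theta,
                )
            )
            break
    return cells


def _render(params, geo, planned_cells, rng) -> np.ndarray:
    n = params.image_size_px
    px = params.calibration.pixel_size_um
    rgb = np.empty((n, n, 3), dtype=np.uint8)
    rgb[:] = _COLORS["background"]
    tissue = geo["tissue"]
    rgb[tissue] = _COLORS["stroma"]
    rgb[geo["tub_label"] > 0] = _COLORS["tubule"]
    for m, (cy, cx, a, b, th) in geo["art_shapes"]:
        rgb[m] = _COLORS["artery_wall"]
        rr, cc = draw_ellipse(cy, cx, a * 0.5, b * 0.5, rotation=th, shape=(n, n))
        rgb[rr, cc] = _COLORS["artery_lumen"]
    for m, (cy, cx, a, b, th) in geo["glom_shapes"]:
        rgb[m] = _COLORS["capsule"]
        rr, cc = draw_ellipse(cy, cx, a * 0.94, b * 0.94, rotation=th, shape=(n, n))
        rgb[rr, cc] = _COLORS["bowman_space"]
        rr, cc = draw_ellipse(cy, cx, a * 0.82, b * 0.82, rotation=th, shape=(n, n))
        rgb[rr, cc] = _COLORS["glom_tuft"]
    for cell, theta in planned_cells:
        cx_um, cy_um = cell.centroid_um
        rr, cc = draw_ellipse(
            cy_um / px, cx_um / px,
            cell.semi_axis_major_um / px, cell.semi_axis_minor_um / px,
            rotation=theta, shape=(n, n),
        )
        rgb[rr, cc] = _tinted_gray(cell.mean_brightness)
    if params.noise_sigma > 0:
        noise = rng.normal(0, params.noise_sigma, size=rgb.shape)
        rgb = np.clip(rgb.astype(float) + noise, 0, 255).astype(np.uint8)
    return rgb


# -- oracle and corruption -------------------------------------------------


def oracle_segmenter(
    slide: SynthSlide, tile: tuple[int, int, int, int]
) -> list[InstanceMask]:
    """Ground-truth instances clipped to a half-open tile box, score 1.0."""
    x0, y0, x1, y1 = tile
    n = slide.params.image_size_px
    if not (0 <= x0 < x1 <= n and 0 <= y0 < y1 <= n):
        raise ValueError(f"tile {tile} out of slide bounds (0, 0, {n}, {n})")
    out = []
    for inst in slide.instances:
        clipped = inst.clipped(tile)
        if clipped is not None:
            out.append(clipped)
    return out


def make_oracle_segmenter(slide: SynthSlide):
    """Wrap a slide's ground truth as a pipeline segmenter.

    The returned callable honors the segmenter contract
    ``(tile_rgb, calibration, box) -> instances in tile coordinates``.
    """

    def segmenter(tile_rgb, calibration, box):
        x0, y0, _, _ = box
        return [inst.translated(-x0, -y0) for inst in oracle_segmenter(slide, box)]

    return segmenter


def corrupt_segmentation(
    instances: list[InstanceMask],
    dropout_rate: float = 0.0,
    boundary_jitter_um: float = 0.0,
    seed: int = 0,
    calibration: PixelCalibration = X20_CALIBRATION,
) -> list[InstanceMask]:
    """Degrade a segmentation: random instance dropout and boundary jitter.

    Each instance is removed with probability ``dropout_rate``; survivors
    are eroded or dilated by a uniformly drawn amount up to
    ``boundary_jitter_um``. Deterministic under the seed. Instances eroded
    to nothing are dropped.
    """
    if not (0 <= dropout_rate <= 1):
        raise ValueError("dropout_rate must be in [0, 1]")
    if boundary_jitter_um < 0:
        raise ValueError("boundary_jitter_um must be >= 0")
    rng = np.random.default_rng(seed)
    j_px = microns_to_pixels(boundary_jitter_um, calibration)
    out = []
    for inst in instances:
        if rng.random() < dropout_rate:
            continue
        if j_px == 0:
            out.append(inst)
            continue
        amount = int(rng.integers(-j_px, j_px + 1))
        if amount == 0:
            out.append(inst)
            continue
        x0, y0, x1, y1 = inst.bbox
        pad = abs(amount) + 1
        padded = np.zeros((y1 - y0 + 2 * pad, x1 - x0 + 2 * pad), dtype=bool)
        padded[pad:-pad, pad:-pad] = inst.mask
        footprint = disk(abs(amount))
        if amount > 0:
            new = dilation(padded, footprint)
        else:
            new = erosion(padded, footprint)
        if not new.any():
            continue
        out.append(
            InstanceMask.from_full_mask(
                inst.class_label, new, inst.score, origin=(x0 - pad, y0 - pad)
            )
        )
    return out
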