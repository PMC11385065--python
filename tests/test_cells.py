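import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from renalmorph import (
    CellObject,
    ClassLabel,
    LabelMap,
    PipelineConfig,
    PixelCalibration,
    compute_morphometry,
    detect_cells,
    map_infiltration,
    tile_is_infiltrated,
)
from renalmorph.config import X20_CALIBRATION
from renalmorph.synthetic import _tinted_gray

STROMA_RGB = (243, 205, 215)


def stroma_scene(shape=(200, 200), calib=X20_CALIBRATION):
    """An all-stroma image + label map to draw test cells onto."""
    rgb = np.empty(shape + (3,), dtype=np.uint8)
    rgb[:] = STROMA_RGB
    raster = np.full(shape, int(ClassLabel.stroma), dtype=np.uint8)
    return rgb, LabelMap(raster, calib)


def draw_cell(rgb, cy, cx, semi_major_um, semi_minor_um, gray, calib=X20_CALIBRATION, theta=0.3):
    px = calib.pixel_size_um
    rr, cc = draw_ellipse(
        cy, cx, semi_major_um / px, semi_minor_um / px, rotation=theta,
        shape=rgb.shape[:2],
    )
    rgb[rr, cc] = _tinted_gray(gray)


class TestDetectCells:
    def test_round_dark_small_object_is_lymphocyte(self):
        rgb, lm = stroma_scene()
        draw_cell(rgb, 100, 100, 3.6, 3.0, gray=70)  # ratio 1.2, dia ~7 µm
        cells = detect_cells(rgb, lm, PipelineConfig())
        assert [c.cell_type for c in cells] == ["lymphocyte"]
        assert cells[0].mean_brightness < 95
        assert cells[0].axis_ratio < 2

    def test_elongated_object_is_nucleus_even_if_dark(self):
        rgb, lm = stroma_scene()
        draw_cell(rgb, 100, 100, 6.3, 2.5, gray=70)  # ratio 2.5
        cells = detect_cells(rgb, lm, PipelineConfig())
        assert [c.cell_type for c in cells] == ["nucleus"]

    def test_bright_round_object_is_nucleus(self):
        rgb, lm = stroma_scene()
        draw_cell(rgb, 100, 100, 3.6, 3.0, gray=120)  # ratio 1.2, too bright
        cells = detect_cells(rgb, lm, PipelineConfig())
        assert [c.cell_type for c in cells] == ["nucleus"]

    def test_objects_outside_stroma_ignored(self):
        rgb, lm = stroma_scene()
        lm.raster[:, :100] = int(ClassLabel.tubuli)
        draw_cell(rgb, 100, 50, 3.6, 3.0, gray=70)  # inside a tubule
        draw_cell(rgb, 100, 150, 3.6, 3.0, gray=70)  # in stroma
        cells = detect_cells(rgb, lm, PipelineConfig())
        assert len(cells) == 1
        assert cells[0].centroid_um[0] > 100 * X20_CALIBRATION.pixel_size_um

    def test_touching_cells_split_by_watershed(self):
        rgb, lm = stroma_scene()
        draw_cell(rgb, 100, 96, 3.3, 3.0, gray=70, theta=0)
        draw_cell(rgb, 100, 109, 3.3, 3.0, gray=70, theta=0)  # touching pair
        cells = detect_cells(rgb, lm, PipelineConfig())
        assert len(cells) == 2

    def test_translation_invariance(self):
        rgb, lm = stroma_scene((260, 260))
        for cy, cx, g in [(60, 70, 70), (120, 140, 120)]:
            draw_cell(rgb, cy, cx, 3.5, 3.0, gray=g)
        cells = detect_cells(rgb, lm, PipelineConfig())
        dy, dx = 31, 17
        shifted = np.empty_like(rgb)
        shifted[:] = STROMA_RGB
        shifted[dy:, dx:] = rgb[:-dy, :-dx]
        cells2 = detect_cells(shifted, lm, PipelineConfig())
        assert len(cells) == len(cells2) == 2
        px = X20_CALIBRATION.pixel_size_um
        for a, b in zip(
            sorted(cells, key=lambda c: c.centroid_um),
            sorted(cells2, key=lambda c: c.centroid_um),
        ):
            assert b.centroid_um[0] - a.centroid_um[0] == pytest.approx(dx * px, abs=1e-6)
            assert b.centroid_um[1] - a.centroid_um[1] == pytest.approx(dy * px, abs=1e-6)
            assert a.cell_type == b.cell_type


def make_cell(x_um, y_um, kind):
    return CellObject(
        centroid_um=(x_um, y_um),
        semi_axis_major_um=3.0,
        semi_axis_minor_um=2.8,
        mean_brightness=70.0 if kind == "lymphocyte" else 120.0,
        area_um2=26.0,
        cell_type=kind,
    )


class TestInfiltrationRule:
    def test_rule_conjunction_spot_cases(self):
        assert tile_is_infiltrated(2, 18)  # 2 lymphocytes, 20 cells total
        assert not tile_is_infiltrated(1, 100)  # too few lymphocytes
        assert not tile_is_infiltrated(0, 0)
        assert tile_is_infiltrated(20, 0)  # lymphocytes alone can reach 20

    def test_strict_nucleus_reading_toggle(self):
        cfg = PipelineConfig(count_lymphocytes_as_nuclei=False)
        assert not tile_is_infiltrated(2, 18, cfg)
        assert tile_is_infiltrated(2, 20, cfg)


class TestMapInfiltration:
    def make_scene(self):
        # 100x100 µm ROI at x20: 198x198 px, two 99-px tiles per axis
        n = 198
        raster = np.full((n, n), int(ClassLabel.stroma), dtype=np.uint8)
        return LabelMap(raster, X20_CALIBRATION)

    def test_single_flagged_tile_in_full_stroma_is_25_pct(self):
        lm = self.make_scene()
        cells = [make_cell(5 + i, 5.0, "lymphocyte") for i in range(2)]
        cells += [make_cell(10 + i, 10.0, "nucleus") for i in range(18)]
        mask, flags, n_tiles = map_infiltration(cells, lm, PipelineConfig())
        assert n_tiles == 1 and flags[0, 0]
        report = compute_morphometry(lm, cells=cells, n_infiltration_tiles=n_tiles)
        assert report.infiltration_rel_area_pct == 25.0
        assert report.n_lymphocytes == 2 and report.n_nuclei == 18

    def test_cells_spread_over_tiles_not_flagged(self):
        lm = self.make_scene()
        # 2 lymphocytes in one tile, 18 nuclei in another: neither qualifies
        cells = [make_cell(5 + i, 5.0, "lymphocyte") for i in range(2)]
        cells += [make_cell(60 + i, 60.0, "nucleus") for i in range(18)]
        mask, flags, n_tiles = map_infiltration(cells, lm, PipelineConfig())
        assert n_tiles == 0 and not mask.any()

    def test_infiltration_confined_to_eligible_stroma(self):
        lm = self.make_scene()
        lm.raster[:99, :50] = int(ClassLabel.proper_stroma)
        cells = [make_cell(5 + i, 5.0, "lymphocyte") for i in range(2)]
        cells += [make_cell(10 + i, 10.0, "nucleus") for i in range(18)]
        mask, _, _ = map_infiltration(cells, lm, PipelineConfig())
        assert mask.any()
        assert not mask[:99, :50].any()  # proper stroma stays excluded

    def test_removing_lymphocytes_zeroes_infiltration_keeps_fibrosis(self):
        lm = self.make_scene()
        cells = [make_cell(5 + i, 5.0, "lymphocyte") for i in range(3)]
        cells += [make_cell(10 + i, 10.0, "nucleus") for i in range(20)]
        map_infiltration(cells, lm, PipelineConfig())
        with_l = compute_morphometry(lm, cells=cells)
        lm2 = self.make_scene()
        nuclei_only = [c for c in cells if c.cell_type == "nucleus"]
        map_infiltration(nuclei_only, lm2, PipelineConfig())
        without_l = compute_morphometry(lm2, cells=nuclei_only)
        assert with_l.infiltration_rel_area_pct > 0
        assert without_l.infiltration_rel_area_pct == 0
        assert without_l.fibrosis_rel_area_pct == with_l.fibrosis_rel_area_pct == 100.0


class TestComputeMorphometry:
    def test_no_stroma_beyond_proper_gives_zero_fibrosis(self):
        raster = np.full((50, 50), int(ClassLabel.proper_stroma), dtype=np.uint8)
        raster[:10] = int(ClassLabel.tubuli)
        lm = LabelMap(raster, X20_CALIBRATION)
        report = compute_morphometry(lm)
        assert report.fibrosis_rel_area_pct == 0.0

    def test_empty_tissue_raises(self):
        raster = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ZeroDivisionError):
            compute_morphometry(LabelMap(raster, X20_CALIBRATION))

    def test_recovery_on_oracle_segmentation(self, slide7, analysis7):
        # copy: the session label map must stay pristine for other tests
        lm = LabelMap(
            analysis7["label_map"].raster.copy(), analysis7["calibration"]
        )
        cells = detect_cells(slide7.rgb_image, lm, analysis7["config"])
        _, _, n_tiles = map_infiltration(cells, lm, analysis7["config"])
        report = compute_morphometry(lm, cells=cells, n_infiltration_tiles=n_tiles)
        assert abs(report.fibrosis_rel_area_pct - slide7.true_fibrosis_pct) <= 3.0
        assert abs(report.infiltration_rel_area_pct - slide7.true_infiltration_pct) <= 3.0
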