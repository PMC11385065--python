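import numpy as np
import pytest

from renalmorph import ClassLabel
from renalmorph.synthetic import (
    InfeasibleTargetsError,
    SynthParams,
    corrupt_segmentation,
    generate_slide,
    oracle_segmenter,
)


def small_params(**kwargs):
    defaults = dict(
        image_size_px=640,
        fibrosis_fraction_target=0.18,
        infiltration_fraction_target=0.03,
        seed=11,
    )
    defaults.update(kwargs)
    return SynthParams(**defaults)


class TestGenerateSlide:
    def test_deterministic_under_seed(self):
        a = generate_slide(small_params())
        b = generate_slide(small_params())
        assert np.array_equal(a.rgb_image, b.rgb_image)
        assert np.array_equal(a.ground_truth.raster, b.ground_truth.raster)
        assert a.true_fibrosis_pct == b.true_fibrosis_pct
        assert len(a.cells) == len(b.cells)

    def test_zero_fibrosis_target(self):
        s = generate_slide(
            small_params(fibrosis_fraction_target=0.0, infiltration_fraction_target=0.0)
        )
        assert s.true_fibrosis_pct < 3.0
        assert s.true_infiltration_pct == 0.0

    def test_fibrosis_within_3_points_of_target(self, slide7):
        target = 100 * slide7.params.fibrosis_fraction_target
        assert abs(slide7.true_fibrosis_pct - target) <= 3.0

    def test_class_area_ratio_within_20pct(self, slide7):
        areas = slide7.ground_truth.class_areas_px()
        tub = areas[ClassLabel.tubuli]
        glom = areas[ClassLabel.glomeruli]
        art = areas[ClassLabel.arteries]
        assert 40 / 3 * 0.8 <= tub / glom <= 40 / 3 * 1.2
        assert 40 / 2 * 0.8 <= tub / art <= 40 / 2 * 1.2

    def test_infeasible_targets_raise(self):
        with pytest.raises(InfeasibleTargetsError):
            generate_slide(small_params(infiltration_fraction_target=0.6))

    def test_rendered_lymphocytes_satisfy_detection_rules(self, slide7):
        lymphs = [c for c in slide7.cells if c.cell_type == "lymphocyte"]
        assert lymphs
        for c in lymphs:
            assert c.axis_ratio < 2.0
            assert c.mean_brightness < 95.0

    def test_cells_lie_in_stromal_ground_truth(self, slide7):
        gt = slide7.ground_truth
        px = slide7.params.calibration.pixel_size_um
        stromal = gt.mask(
            ClassLabel.stroma, ClassLabel.proper_stroma, ClassLabel.infiltration
        )
        for c in slide7.cells:
            x, y = c.centroid_um
            assert stromal[int(round(y / px)), int(round(x / px))]

    def test_truth_percentages_match_label_map(self, slide7):
        gt = slide7.ground_truth
        tissue = gt.raster != int(ClassLabel.background)
        fib = gt.mask(ClassLabel.stroma, ClassLabel.infiltration).sum() / tissue.sum()
        inf = gt.mask(ClassLabel.infiltration).sum() / tissue.sum()
        assert slide7.true_fibrosis_pct == pytest.approx(100 * fib)
        assert slide7.true_infiltration_pct == pytest.approx(100 * inf)


class TestOracleSegmenter:
    def test_whole_slide_tile_returns_all_instances(self, slide7):
        n = slide7.params.image_size_px
        out = oracle_segmenter(slide7, (0, 0, n, n))
        assert len(out) == len(slide7.instances)

    def test_pure_background_tile_is_empty(self, slide7):
        # the white border margin holds no structures
        out = oracle_segmenter(slide7, (0, 0, 10, 10))
        assert out == []

    def test_bisecting_tile_clips_to_intersection(self, slide7):
        glom = next(
            i for i in slide7.instances if i.class_label is ClassLabel.glomeruli
        )
        x0, y0, x1, y1 = glom.bbox
        xm = (x0 + x1) // 2
        tile = (x0 - 5, y0 - 5, xm, y1 + 5)
        out = [
            i
            for i in oracle_segmenter(slide7, tile)
            if i.class_label is ClassLabel.glomeruli
        ]
        assert len(out) == 1
        full = np.zeros((slide7.params.image_size_px,) * 2, bool)
        glom.paint(full)
        tile_mask = np.zeros_like(full)
        tile_mask[tile[1] : tile[3], tile[0] : tile[2]] = True
        got = np.zeros_like(full)
        out[0].paint(got)
        assert np.array_equal(got, full & tile_mask)

    def test_out_of_bounds_tile_raises(self, slide7):
        n = slide7.params.image_size_px
        with pytest.raises(ValueError):
            oracle_segmenter(slide7, (0, 0, n + 1, n))


class TestCorruptSegmentation:
    def test_identity_when_no_corruption(self, slide7):
        out = corrupt_segmentation(slide7.instances, 0.0, 0.0, seed=1)
        assert out == slide7.instances

    def test_full_dropout_empties(self, slide7):
        assert corrupt_segmentation(slide7.instances, 1.0, 0.0, seed=1) == []

    def test_seeded_dropout_reproducible_and_matches_draw(self, slide7):
        insts = slide7.instances[:100]
        out1 = corrupt_segmentation(insts, 0.5, 0.0, seed=123)
        out2 = corrupt_segmentation(insts, 0.5, 0.0, seed=123)
        assert len(out1) == len(out2)
        # replay the seeded RNG: kept count must equal the draw exactly
        rng = np.random.default_rng(123)
        kept = sum(1 for _ in insts if rng.random() >= 0.5)
        assert len(out1) == kept

    def test_jitter_changes_boundaries_not_count_much(self, slide7):
        insts = slide7.instances[:30]
        out = corrupt_segmentation(
            insts, 0.0, 2.0, seed=5, calibration=slide7.params.calibration
        )
        assert 0 < len(out) <= len(insts)
        changed = sum(
            1 for a, b in zip(insts, out) if a.area_px != b.area_px or a.bbox != b.bbox
        )
        assert changed > 0
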