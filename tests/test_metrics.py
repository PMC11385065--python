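import numpy as np
import pytest

from renalmorph import (
    ClassLabel,
    ConfusionCounts,
    InstanceMask,
    average_precision,
    confusion_matrix,
    dice_band,
    dice_score,
    mean_average_precision,
)
from renalmorph.metrics import COCO_IOU_THRESHOLDS

from conftest import random_blob_mask


def inst(full, label=ClassLabel.glomeruli, score=1.0):
    return InstanceMask.from_full_mask(label, np.asarray(full, bool), score)


class TestDice:
    def test_hand_evaluated_formula(self):
        # 2*2 / (2*2 + 1 + 1) = 0.6667
        assert dice_score(ConfusionCounts(tp=2, fp=1, fn=1)) == pytest.approx(
            0.6667, abs=1e-4
        )

    def test_identical_masks(self, rng):
        m = random_blob_mask(rng)
        assert dice_score(ConfusionCounts.from_masks(m, m)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = b[5, 5] = True
        assert dice_score(ConfusionCounts.from_masks(a, b)) == 0.0

    def test_both_empty_convention(self):
        assert dice_score(ConfusionCounts(0, 0, 0)) == 1.0

    def test_raster_oracle_equivalence(self):
        # Dice from the confusion counts must equal 2|A∩B|/(|A|+|B|)
        # computed directly on the rasters
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_blob_mask(rng, (15, 15), 0.4)
            b = random_blob_mask(rng, (15, 15), 0.4)
            direct = 2 * np.sum(a & b) / (a.sum() + b.sum())
            assert dice_score(ConfusionCounts.from_masks(a, b)) == pytest.approx(direct)

    @pytest.mark.parametrize(
        "value, band", [(0.9, "good"), (0.81, "good"), (0.7, "acceptable"),
                        (0.6, "acceptable"), (0.5, "bad")]
    )
    def test_quality_bands(self, value, band):
        assert dice_band(value) == band


class TestConfusionMatrix:
    classes = [ClassLabel.glomeruli, ClassLabel.tubuli]

    def test_perfect_prediction_is_identity(self):
        truth = np.array([[1, 1], [2, 2]], dtype=np.uint8)
        m = confusion_matrix(truth, truth, self.classes, normalize=True)
        assert np.allclose(m, np.eye(2))

    def test_total_confusion(self):
        truth = np.full((4, 4), 1, dtype=np.uint8)  # all glomeruli
        pred = np.full((4, 4), 2, dtype=np.uint8)  # all tubuli
        m = confusion_matrix(pred, truth, self.classes, normalize=True)
        assert m[1, 0] == 1.0 and m[0, 0] == 0.0

    def test_four_pixel_enumeration(self):
        # 2 correct A, 1 A predicted as B, 1 correct B
        truth = np.array([[1, 1], [1, 2]], dtype=np.uint8)
        pred = np.array([[1, 1], [2, 2]], dtype=np.uint8)
        m = confusion_matrix(pred, truth, self.classes, normalize=True)
        assert m[:, 0] == pytest.approx([2 / 3, 1 / 3], abs=1e-3)

    def test_columns_sum_to_one(self, rng):
        truth = rng.integers(1, 4, (30, 30)).astype(np.uint8)
        pred = rng.integers(1, 4, (30, 30)).astype(np.uint8)
        classes = [ClassLabel.glomeruli, ClassLabel.tubuli, ClassLabel.arteries]
        m = confusion_matrix(pred, truth, classes, normalize=True)
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="aligned"):
            confusion_matrix(
                np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8), self.classes
            )


class TestAveragePrecision:
    def test_perfect_predictions_give_map_1(self, rng):
        truths = []
        for k in range(4):
            full = np.zeros((40, 40), bool)
            full[k * 9 : k * 9 + 6, 3:9] = True
            truths.append(inst(full))
        result = mean_average_precision(truths, truths)
        assert result.mAP == 1.0

    def test_single_prediction_iou_07(self):
        # IoU 0.7 matches at thresholds 0.50-0.70: five of the ten
        a = np.zeros((10, 10), bool)
        a[:7] = True  # 70 px truth
        b = np.ones((10, 10), bool)  # 100 px pred; inter 70, union 100
        ap = average_precision([inst(b)], [inst(a)])
        assert ap == pytest.approx(0.5)

    def test_no_predictions(self):
        truth = inst(np.ones((5, 5)))
        assert average_precision([], [truth]) == 0.0

    def test_predictions_without_truth(self):
        pred = inst(np.ones((5, 5)))
        assert average_precision([pred], []) == 0.0

    def test_empty_class_excluded_from_mean(self):
        full = np.ones((6, 6), bool)
        truths = [inst(full, ClassLabel.glomeruli)]
        preds = [inst(full, ClassLabel.glomeruli, 0.9)]
        result = mean_average_precision(
            preds, truths, classes=[ClassLabel.glomeruli, ClassLabel.arteries]
        )
        assert result.per_class[ClassLabel.arteries] is None
        assert result.n_classes == 1
        assert result.mAP == 1.0

    def test_mixed_classes_rejected(self):
        a = inst(np.ones((3, 3)), ClassLabel.glomeruli)
        b = inst(np.ones((3, 3)), ClassLabel.tubuli)
        with pytest.raises(ValueError):
            average_precision([a], [b])

    def test_duplicate_predictions_penalized(self):
        full = np.ones((8, 8), bool)
        truth = inst(full)
        dup = [inst(full, score=0.9), inst(full, score=0.8)]
        ap = average_precision(dup, [truth])
        # second prediction is an unmatched false positive; AP stays 1.0
        # under all-point interpolation since recall 1 is reached first
        assert ap == pytest.approx(1.0)
        worse = [inst(full, score=0.8), inst(full, score=0.9)]
        assert average_precision(worse, [truth]) == pytest.approx(1.0)

    def test_threshold_grid_is_coco(self):
        assert len(COCO_IOU_THRESHOLDS) == 10
        assert COCO_IOU_THRESHOLDS[0] == 0.5
        assert COCO_IOU_THRESHOLDS[-1] == pytest.approx(0.95)
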