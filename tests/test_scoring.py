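import numpy as np
import pytest

from renalmorph import (
    SlideRecord,
    predict_score_group,
    roc_analysis,
    spearman_correlation,
)
from renalmorph.scoring import DegenerateLabelsError, read_slide_records, write_slide_records


def records(pairs, score="ci"):
    out = []
    for i, (value, grade) in enumerate(pairs):
        out.append(
            SlideRecord(
                slide_id=f"s{i}",
                infiltration_rel_area_pct=value,
                fibrosis_rel_area_pct=value,
                ci_score=grade if score == "ci" else 0,
                i_score=grade if score == "i" else 0,
            )
        )
    return out


def brute_force_auc(pos, neg):
    """Concordant-pair fraction with ties counted 1/2 (Mann-Whitney)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_perfect_separation(self):
        recs = records([(1, 0), (2, 0), (3, 1), (10, 2), (12, 2), (14, 3)])
        r = roc_analysis(recs, "infiltration", "ci")
        assert r.auc == 1.0
        assert r.sens_at_cutoff == 1.0 and r.spec_at_cutoff == 1.0
        assert r.youden_j_max == 1.0

    def test_uninformative_feature(self):
        recs = records([(5, 0), (5, 1), (5, 2), (5, 3)])
        assert roc_analysis(recs, "infiltration", "ci").auc == 0.5

    def test_brute_force_pair_counting_case(self):
        # positives {10, 12, 14}, negatives {1, 2, 11}: 8 of 9 pairs concordant
        recs = records([(1, 0), (2, 1), (11, 0), (10, 2), (12, 3), (14, 2)])
        r = roc_analysis(recs, "infiltration", "ci")
        assert r.auc == pytest.approx(8 / 9)

    def test_one_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_analysis(records([(1, 0), (2, 1)]), "infiltration", "ci")

    def test_auc_equals_pair_counting_on_random_cohorts(self):
        # trapezoid AUC must agree with the Mann-Whitney oracle
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_pos, n_neg = rng.integers(2, 8, 2)
            pos = rng.integers(0, 10, n_pos).astype(float)
            neg = rng.integers(0, 10, n_neg).astype(float)
            r = roc_analysis(
                values=np.concatenate([pos, neg]),
                labels=[1] * len(pos) + [0] * len(neg),
            )
            assert r.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.random(40) * 50
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        r1 = roc_analysis(values=values, labels=labels)
        r2 = roc_analysis(values=np.exp(values / 10), labels=labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert r1.youden_j_max == pytest.approx(r2.youden_j_max)

    def test_youden_definition(self):
        recs = records([(1, 0), (4, 0), (6, 2), (3, 2), (8, 3)])
        r = roc_analysis(recs, "infiltration", "ci")
        j = r.sensitivities + r.specificities - 1
        assert r.youden_j_max == pytest.approx(j.max())
        assert r.sens_at_cutoff + r.spec_at_cutoff - 1 == pytest.approx(r.youden_j_max)


class TestPredictScoreGroup:
    def test_boundary_is_high(self):
        assert predict_score_group(5.0, 5.0) == "high"

    def test_below_cutoff_low(self):
        assert predict_score_group(0.0, 5.0) == "low"

    def test_cutoff_separates_training_groups_when_separable(self):
        recs = records([(1, 0), (2, 1), (10, 2), (12, 3)])
        r = roc_analysis(recs, "infiltration", "ci")
        for rec in recs:
            expected = "high" if rec.ci_score >= 2 else "low"
            assert predict_score_group(rec.feature("infiltration"), r.optimal_cutoff) == expected


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = [1.0, 2.5, 4.0, 7.0, 9.0]
        y = [np.exp(v) for v in x]  # nonlinear but strictly monotone
        assert spearman_correlation(x, y) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_brute_force_rank_formula(self):
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/60 = 0.6
        assert spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [3, 4])


class TestSlideRecordCsv:
    def test_round_trip(self, tmp_path):
        recs = records([(1.5, 0), (22.25, 2), (8.0, 1), (30.0, 3)])
        path = tmp_path / "slides.csv"
        write_slide_records(recs, path)
        assert read_slide_records(path) == recs

    def test_validation(self):
        with pytest.raises(ValueError):
            SlideRecord("s", 150.0, 10.0, 0, 0)
        with pytest.raises(ValueError):
            SlideRecord("s", 10.0, 10.0, 4, 0)
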