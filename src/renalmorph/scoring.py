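"""Discrimination of Banff score groups from measured morphometry.

Per-slide relative areas of fibrosis and interstitial infiltration are
compared against expert Banff ci / i scores. Slides with score 2-3 form the
positive group, 0-1 the negative group; a ROC curve over the measured area
gives the AUC and the Youden-optimal cutoff (maximizing sensitivity +
specificity - 1) with its sensitivity and specificity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "SlideRecord",
    "RocResult",
    "roc_analysis",
    "predict_score_group",
    "spearman_correlation",
    "read_slide_records",
    "write_slide_records",
]

Feature = Literal["infiltration", "fibrosis"]
Score = Literal["ci", "i"]


class DegenerateLabelsError(ValueError):
    """ROC requested with only one score group present."""


@dataclass(frozen=True)
class SlideRecord:
    """Measured areas plus expert Banff scores for one slide."""

    slide_id: str
    infiltration_rel_area_pct: float
    fibrosis_rel_area_pct: float
    ci_score: int
    i_score: int

    def __post_init__(self) -> None:
        for name in ("ci_score", "i_score"):
            if getattr(self, name) not in (0, 1, 2, 3):
                raise ValueError(f"{name} must be one of 0-3")
        for name in ("infiltration_rel_area_pct", "fibrosis_rel_area_pct"):
            if not (0 <= getattr(self, name) <= 100):
                raise ValueError(f"{name} must be in [0, 100]")

    def feature(self, which: Feature) -> float:
        return getattr(self, f"{which}_rel_area_pct")

    def group(self, score: Score) -> int:
        """1 for the high (2-3) score group, 0 for low (0-1)."""
        return int(getattr(self, f"{score}_score") >= 2)


@dataclass
class RocResult:
    """ROC curve summary for one feature/score pairing.

    ``optimal_cutoff`` is in feature units (percent area); ``youden_j_max``
    is the dimensionless J statistic sens + spec - 1 at that cutoff. The
    two are reported under distinct names because they are different
    quantities. Sensitivity/specificity are fractions in [0, 1].
    """

    feature: str
    score: str
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    youden_j_max: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_positive: int = 0
    n_negative: int = 0

    def summary(self) -> dict:
        return {
            "feature": self.feature,
            "score": self.score,
            "auc": round(self.auc, 4),
            "optimal_cutoff_pct": round(self.optimal_cutoff, 4),
            "youden_j_max": round(self.youden_j_max, 4),
            "sensitivity_pct": round(100 * self.sens_at_cutoff, 2),
            "specificity_pct": round(100 * self.spec_at_cutoff, 2),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def roc_analysis(
    records: Sequence[SlideRecord] | None = None,
    feature: Feature = "infiltration",
    score: Score = "ci",
    *,
    values: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> RocResult:
    """ROC for predicting score 2-3 vs 0-1 from a measured area.

    Either pass ``records`` with the feature/score names, or raw
    ``values``/``labels`` arrays. The decision rule is value >= cutoff ->
    positive; AUC is the trapezoid area, equal to the Mann-Whitney
    concordant-pair fraction.
    """
    if records is not None:
        values = [r.feature(feature) for r in records]
        labels = [r.group(score) for r in records]
    y = np.asarray(labels, dtype=int)
    x = np.asarray(values, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"both score groups must be nonempty (positives={n_pos}, negatives={n_neg})"
        )
    fpr, tpr, thr = roc_curve(y, x, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        feature=feature if records is not None else "feature",
        score=score if records is not None else "label",
        thresholds=thr,
        sensitivities=tpr,
        specificities=1 - fpr,
        auc=auc,
        youden_j_max=float(j[best]),
        optimal_cutoff=float(thr[best]),
        sens_at_cutoff=float(tpr[best]),
        spec_at_cutoff=float(1 - fpr[best]),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def predict_score_group(value: float, cutoff: float) -> str:
    """Classify a measured area: 'high' (score 2-3) iff value >= cutoff."""
    return "high" if value >= cutoff else "low"


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# -- CSV interface ---------------------------------------------------------

_CSV_FIELDS = [
    "slide_id",
    "infiltration_rel_area_pct",
    "fibrosis_rel_area_pct",
    "ci_score",
    "i_score",
]


def write_slide_records(records: Iterable[SlideRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for r in records:
            writer.writerow({k: getattr(r, k) for k in _CSV_FIELDS})


def read_slide_records(path: str | Path) -> list[SlideRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SlideRecord(
                    slide_id=row["slide_id"],
                    infiltration_rel_area_pct=float(row["infiltration_rel_area_pct"]),
                    fibrosis_rel_area_pct=float(row["fibrosis_rel_area_pct"]),
                    ci_score=int(row["ci_score"]),
                    i_score=int(row["i_score"]),
                )
            )
    return out
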