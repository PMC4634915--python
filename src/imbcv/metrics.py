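"""Performance measures for one cross-validation fold.

Six measures, all defined with respect to the minority (positive) class:
overall predictive accuracy PA, its class-restricted versions PA_min and
PA_maj, their geometric mean GM = sqrt(PA_min * PA_maj), the F1 measure
F1 = 2 * Precision * PA_min / (Precision + PA_min), and AUC.  Precision
(the minority-class predictive value) is reported as well since F1 is built
from it.

AUC is computed as the Mann–Whitney rank statistic — the probability that a
randomly chosen minority sample scores above a randomly chosen majority
sample, with ties counted 1/2 — rather than by integrating an ROC curve; the
two are identical and the rank form makes the tie convention explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["FoldPredictions", "PerformanceMeasures", "compute_measures", "MEASURE_NAMES"]

MEASURE_NAMES = ("PA", "PA_min", "PA_maj", "GM", "F1", "AUC")


@dataclass(frozen=True)
class FoldPredictions:
    """Truths, hard predictions and minority scores for the samples of one fold."""

    true_labels: np.ndarray
    predicted_classes: np.ndarray
    minority_scores: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.true_labels)
        c = np.asarray(self.predicted_classes)
        s = np.asarray(self.minority_scores, dtype=float)
        if not (len(t) == len(c) == len(s)) or len(t) < 1:
            raise ValueError("prediction vectors must share a positive length")
        object.__setattr__(self, "true_labels", t)
        object.__setattr__(self, "predicted_classes", c)
        object.__setattr__(self, "minority_scores", s)


@dataclass(frozen=True)
class PerformanceMeasures:
    PA: float
    PA_min: float
    PA_maj: float
    GM: float
    F1: float
    AUC: float
    Precision: float

    def as_dict(self) -> dict[str, float]:
        return {
            "PA": self.PA,
            "PA_min": self.PA_min,
            "PA_maj": self.PA_maj,
            "GM": self.GM,
            "F1": self.F1,
            "AUC": self.AUC,
            "Precision": self.Precision,
        }


def mann_whitney_auc(true_labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized rank-sum of minority scores, ties counted 1/2."""
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=float)
    n_min = int(np.sum(true_labels == 1))
    n_maj = int(np.sum(true_labels == 0))
    if n_min == 0 or n_maj == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum = float(np.sum(ranks[true_labels == 1]))
    return (rank_sum - n_min * (n_min + 1) / 2) / (n_min * n_maj)


def compute_measures(pred: FoldPredictions) -> PerformanceMeasures:
    """Compute the six measures (plus Precision) from one fold's predictions.

    Raises if the fold truth contains a single class — the caller decides how
    to handle such degenerate folds.  F1 is defined as 0 when
    Precision + PA_min = 0 (no minority sample predicted or recovered).
    """
    t = pred.true_labels
    is_min = t == 1
    n_min = int(is_min.sum())
    n_maj = len(t) - n_min
    if n_min == 0 or n_maj == 0:
        raise ValueError("fold truth contains a single class; measures undefined")

    correct = pred.predicted_classes == t
    pa = float(correct.mean())
    pa_min = float(correct[is_min].mean())
    pa_maj = float(correct[~is_min].mean())
    gm = float(np.sqrt(pa_min * pa_maj))

    predicted_min = pred.predicted_classes == 1
    n_pred_min = int(predicted_min.sum())
    precision = float(correct[predicted_min].mean()) if n_pred_min else 0.0
    denom = precision + pa_min
    f1 = 2.0 * precision * pa_min / denom if denom > 0 else 0.0

    auc = mann_whitney_auc(t, pred.minority_scores)
    return PerformanceMeasures(pa, pa_min, pa_maj, gm, f1, auc, precision)
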