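"""Sensitivity/specificity and ROC/AUC against a FISH truth table.

Prediction scores are per-event SV support counts; sweeping a threshold
over them traces the ROC curve. The area under the curve is computed by
the trapezoid rule over the threshold sweep, which assigns tied scores
half credit and therefore coincides with the Mann-Whitney concordance
probability P(score+ > score-) + 0.5 P(tie). Confidence intervals come
from a percentile bootstrap over (sample, event) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from svconcord.cytogenetics import PredictionMatrix
from svconcord.io import TruthTable


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts at a fixed threshold."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def P(self) -> int:
        """Positive cells in the truth labels."""
        return self.TP + self.FN

    @property
    def N(self) -> int:
        """Negative cells in the truth labels."""
        return self.FP + self.TN

    @property
    def sensitivity(self) -> float:
        """TP / P — the true positive rate."""
        return self.TP / self.P if self.P else math.nan

    @property
    def specificity(self) -> float:
        """TN / N — one minus the false positive rate."""
        return self.TN / self.N if self.N else math.nan


@dataclass(frozen=True)
class ROCResult:
    """A threshold-swept ROC curve with trapezoid AUC and bootstrap CI."""

    thresholds: np.ndarray  # descending; leading +inf sentinel
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    P: int = 0
    N: int = 0


def _aligned_vectors(pred: PredictionMatrix, truth: TruthTable) -> tuple:
    """Flatten prediction and truth over their common grid; error on mismatch."""
    missing = [
        (s, e)
        for s in truth.samples
        for e in truth.events
        if s not in pred.table.index or e not in pred.table.columns
    ]
    extra = [
        (s, e)
        for s in pred.samples
        for e in pred.events
        if s not in truth.table.index or e not in truth.table.columns
    ]
    if missing or extra:
        raise ValueError(
            "prediction and truth grids differ; "
            f"cells missing from predictions: {missing[:5]}, "
            f"cells missing from truth: {extra[:5]}"
        )
    aligned = pred.table.loc[truth.samples, truth.events]
    scores = aligned.values.astype(float).ravel()
    labels = truth.table.values.astype(int).ravel()
    return scores, labels


def confusion_at_threshold(
    pred: PredictionMatrix, truth: TruthTable, threshold: float
) -> ConfusionCounts:
    """Confusion counts with "predicted positive" defined as score >= threshold."""
    scores, labels = _aligned_vectors(pred, truth)
    called = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(called & (labels == 1))),
        FP=int(np.sum(called & (labels == 0))),
        TN=int(np.sum(~called & (labels == 0))),
        FN=int(np.sum(~called & (labels == 1))),
    )


def _curve_from_vectors(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """Threshold-swept (thresholds, tpr, fpr, auc) from flat score/label vectors."""
    P = int(np.sum(labels == 1))
    N = int(np.sum(labels == 0))
    if P == 0 or N == 0:
        raise ValueError(f"ROC undefined: P={P}, N={N} (need at least one of each)")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels == 1)
    cum_fp = np.cumsum(sorted_labels == 0)
    # last index of each run of tied scores: the curve point at that threshold
    last = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate((last, [len(sorted_scores) - 1]))
    thresholds = np.concatenate(([np.inf], sorted_scores[idx]))
    tpr = np.concatenate(([0.0], cum_tp[idx] / P))
    fpr = np.concatenate(([0.0], cum_fp[idx] / N))
    auc = float(np.trapezoid(tpr, fpr))
    return thresholds, tpr, fpr, auc


def roc_curve(
    pred: PredictionMatrix,
    truth: TruthTable,
    n_boot: int = 0,
    seed: Optional[int] = None,
) -> ROCResult:
    """ROC curve and trapezoid AUC of a prediction matrix against truth labels.

    One curve point per unique score plus the (0,0) endpoint; the final
    point (threshold = minimum score, everything called positive) is
    always (1,1). Requires at least one positive and one negative cell.
    Set ``n_boot`` > 0 to attach a percentile-bootstrap CI.
    """
    scores, labels = _aligned_vectors(pred, truth)
    thresholds, tpr, fpr, auc = _curve_from_vectors(scores, labels)
    ci_low = ci_high = None
    if n_boot:
        ci_low, ci_high = _bootstrap_ci(scores, labels, n_boot, seed)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        P=int(np.sum(labels == 1)),
        N=int(np.sum(labels == 0)),
    )


def _bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int,
    seed: Optional[int],
    level: float = 0.95,
) -> tuple:
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(n_boot)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():  # degenerate resample: no positives or no negatives
            continue
        _, _, _, aucs[i] = _curve_from_vectors(scores[idx], lab)
        i += 1
    alpha = (1 - level) / 2
    return (
        float(np.quantile(aucs, alpha)),
        float(np.quantile(aucs, 1 - alpha)),
    )


def bootstrap_auc_ci(
    pred: PredictionMatrix,
    truth: TruthTable,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile-bootstrap confidence interval for the AUC.

    (sample, event) cells are resampled with replacement; resamples with
    no positives or no negatives are redrawn. Reproducible under a fixed
    seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores, labels = _aligned_vectors(pred, truth)
    return _bootstrap_ci(scores, labels, n_boot, seed, level)
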