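"""Agreement and classification statistics.

Confusion matrices, accuracy/precision/recall/F1, Cohen's kappa,
McNemar's paired test and a score-based binary ROC AUC.  Standard
computations are delegated to scikit-learn / scipy; this module fixes
the conventions used throughout the package (rows = truth, columns =
prediction; division-by-zero yields 0 with a warning flag rather than
an exception).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix as _sk_confusion_matrix,
    roc_auc_score,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square contingency table; rows are truth, columns predictions."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(self.labels):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(cls, truth: Sequence[str], predicted: Sequence[str],
                    labels: Sequence[str] | None = None) -> "ConfusionMatrix":
        if len(truth) != len(predicted):
            raise ValueError("length mismatch between truth and predictions")
        if len(truth) == 0:
            raise ValueError("empty input")
        if labels is None:
            labels = sorted(set(truth) | set(predicted))
        counts = _sk_confusion_matrix(truth, predicted, labels=list(labels))
        return cls(labels=tuple(labels), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_label_pairs(self) -> tuple[list[str], list[str]]:
        """Expand back to (truth, predicted) label vectors."""
        truth: list[str] = []
        pred: list[str] = []
        for i, t in enumerate(self.labels):
            for j, p in enumerate(self.labels):
                k = int(self.counts[i, j])
                truth.extend([t] * k)
                pred.extend([p] * k)
        return truth, pred


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    zero_division: bool = False


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus per-class precision/recall/F1 for one prediction set."""

    accuracy: float
    positive_class: str
    per_class: dict[str, ClassMetrics]
    confusion: ConfusionMatrix

    @property
    def precision(self) -> float:
        return self.per_class[self.positive_class].precision

    @property
    def recall(self) -> float:
        return self.per_class[self.positive_class].recall

    @property
    def f1(self) -> float:
        return self.per_class[self.positive_class].f1


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def confusion_and_metrics(truth: Sequence[str], predicted: Sequence[str],
                          positive_class: str,
                          labels: Sequence[str] | None = None) -> MetricsReport:
    """Confusion matrix and the usual derived classification metrics.

    ``positive_class`` selects which class the report's top-level
    precision/recall/F1 refer to; per-class values are always included.
    Undefined ratios (empty denominators) are reported as 0.0 with the
    class's ``zero_division`` flag set, and a warning is emitted.
    """
    cm = ConfusionMatrix.from_labels(truth, predicted, labels=labels)
    if positive_class not in cm.labels:
        raise ValueError(f"positive_class {positive_class!r} not among labels {cm.labels}")
    accuracy = float(np.trace(cm.counts)) / cm.total
    per_class: dict[str, ClassMetrics] = {}
    for i, label in enumerate(cm.labels):
        tp = float(cm.counts[i, i])
        fp = float(cm.counts[:, i].sum() - tp)
        fn = float(cm.counts[i, :].sum() - tp)
        precision, z1 = _safe_div(tp, tp + fp)
        recall, z2 = _safe_div(tp, tp + fn)
        f1, z3 = _safe_div(2 * precision * recall, precision + recall)
        flagged = z1 or z2 or z3
        if flagged:
            warnings.warn(f"zero-division in metrics for class {label!r}; reported as 0.0",
                          RuntimeWarning, stacklevel=2)
        per_class[label] = ClassMetrics(precision=precision, recall=recall,
                                        f1=f1, zero_division=flagged)
    return MetricsReport(accuracy=accuracy, positive_class=positive_class,
                         per_class=per_class, confusion=cm)


def metrics_from_confusion(cm: ConfusionMatrix, positive_class: str) -> MetricsReport:
    """Metrics computed from an already-tabulated confusion matrix."""
    truth, pred = cm.to_label_pairs()
    return confusion_and_metrics(truth, pred, positive_class, labels=cm.labels)


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Unweighted Cohen's kappa between two label vectors.

    Returns exactly 1.0 for perfect agreement; if expected agreement is
    1 (both raters constant) the chance-corrected value is undefined
    and 0.0 is returned as the sentinel.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("length mismatch")
    if len(labels_a) == 0:
        raise ValueError("empty input")
    a = list(labels_a)
    b = list(labels_b)
    if a == b:
        return 1.0
    label_set = sorted(set(a) | set(b))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = cohen_kappa_score(a, b, labels=label_set)
    if np.isnan(kappa):
        return 0.0
    return float(kappa)


@dataclass(frozen=True)
class PairedBinaryOutcomes:
    """Paired per-item correctness of two methods against a shared truth."""

    both_correct: int
    a_only: int
    b_only: int
    both_wrong: int

    def __post_init__(self) -> None:
        for v in (self.both_correct, self.a_only, self.b_only, self.both_wrong):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, truth: Sequence[str], pred_a: Sequence[str],
                         pred_b: Sequence[str]) -> "PairedBinaryOutcomes":
        if not (len(truth) == len(pred_a) == len(pred_b)):
            raise ValueError("length mismatch")
        ok_a = np.asarray([t == p for t, p in zip(truth, pred_a)])
        ok_b = np.asarray([t == p for t, p in zip(truth, pred_b)])
        return cls(both_correct=int((ok_a & ok_b).sum()),
                   a_only=int((ok_a & ~ok_b).sum()),
                   b_only=int((~ok_a & ok_b).sum()),
                   both_wrong=int((~ok_a & ~ok_b).sum()))

    @property
    def n(self) -> int:
        return self.both_correct + self.a_only + self.b_only + self.both_wrong


def mcnemar_test(paired: PairedBinaryOutcomes,
                 method: str = "auto") -> tuple[float | None, float]:
    """McNemar's test on the discordant pairs of two paired classifiers.

    ``exact``: two-sided binomial test on (b, b+c, 1/2) where b, c are
    the discordant counts.  ``chi2``: continuity-corrected statistic
    (|b-c|-1)^2/(b+c) on 1 df.  ``auto`` uses the exact test when
    b + c < 25.  Returns (statistic, p); the exact test has no chi-square
    statistic, so it returns (None, p).
    """
    b, c = paired.a_only, paired.b_only
    nd = b + c
    if nd == 0:
        raise ValueError("no discordant pairs")
    if method not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if nd < 25 else "chi2"
    if method == "exact":
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5))
        return None, float(p)
    statistic = (abs(b - c) - 1.0) ** 2 / nd
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), min(p, 1.0)


def binary_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """ROC AUC of continuous scores against binary truth (ties count 1/2)."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("truth contains a single class; AUC undefined")
    return float(roc_auc_score(y, s))
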