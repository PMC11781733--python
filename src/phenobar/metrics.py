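"""k-class confusion matrices and the three performance indicators.

Every model is scored with three statistics, each expressed as a percentage:

* accuracy: overall percent correctly classified;
* Youden index J, generalized to k classes as the macro-average over
  one-vs-rest collapses of (sensitivity + specificity - 1);
* the Matthews correlation coefficient in its k-class form R_k, the
  correlation between the true and predicted one-hot indicator matrices.

Degenerate denominators (a class never observed or never predicted) score the
affected term as 0 with a log entry rather than failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compounds import ClassLabel
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_CLASS_ORDER = (ClassLabel.AD, ClassLabel.AP, ClassLabel.AX, ClassLabel.CI)


@dataclass(frozen=True)
class ConfusionMatrix:
    class_order: tuple
    counts: np.ndarray  # rows = true, columns = predicted

    def __post_init__(self) -> None:
        k = len(self.class_order)
        counts = np.asarray(self.counts)
        if counts.shape != (k, k):
            raise ValidationError("counts must be k x k")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricSet:
    youden_j: float
    mcc: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {"youden_j": self.youden_j, "mcc": self.mcc, "accuracy": self.accuracy}


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              class_order: Sequence | None = None) -> ConfusionMatrix:
    """Tally a k-class confusion matrix in a fixed class order."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label sequences must have equal length")
    if len(true_labels) == 0:
        raise ValidationError("cannot build a confusion matrix from no samples")
    order = tuple(class_order) if class_order is not None else tuple(
        c for c in DEFAULT_CLASS_ORDER
        if c in set(true_labels) | set(predicted_labels))
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValidationError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(order, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall percent correctly classified."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total * 100.0)


def youden_k(cm: ConfusionMatrix) -> float:
    """Macro-averaged one-vs-rest Youden index, in percent.

    J_k = 100 * [ (1/k) * sum_c (sens_c + spec_c) - 1 ].
    """
    counts = cm.counts
    k = len(cm.class_order)
    total = cm.total
    acc = 0.0
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        if tp + fn == 0 or tn + fp == 0:
            log.debug("youden_k: degenerate class %s scored 0", cm.class_order[c])
        acc += sens + spec
    return float((acc / k - 1.0) * 100.0)


def mcc_k(cm: ConfusionMatrix) -> float:
    """k-class Matthews correlation coefficient (R_k), in percent.

    Computed from the confusion matrix as
    (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)),
    the correlation of the true and predicted indicator matrices.
    """
    counts = cm.counts.astype(float)
    t = counts.sum(axis=1)  # true per class
    p = counts.sum(axis=0)  # predicted per class
    s = counts.sum()
    c = np.trace(counts)
    denom2 = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom2 <= 0:
        log.debug("mcc_k: degenerate denominator, scoring 0")
        return 0.0
    return float((c * s - (p * t).sum()) / np.sqrt(denom2) * 100.0)


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    return MetricSet(youden_j=youden_k(cm), mcc=mcc_k(cm), accuracy=accuracy(cm))
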