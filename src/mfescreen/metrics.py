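"""Cohort-level diagnostic evaluation.

Conventions: AD is the positive class. TP = AD predicted AD, TN = HS
predicted HS, FP = HS predicted AD, FN = AD predicted HS. An indeterminate
prediction (exact index tie) is counted as an error against the true class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError

VALID_TRUE = {"HS", "AD"}
VALID_PRED = {"HS", "AD", "indeterminate"}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionMatrix:
    """Confusion matrix from per-subject true and predicted labels."""
    if len(true_labels) != len(predicted_labels):
        raise ConfigError(
            f"{len(true_labels)} true labels vs {len(predicted_labels)} predictions"
        )
    tp = tn = fp = fn = 0
    for truth, pred in zip(true_labels, predicted_labels):
        if truth not in VALID_TRUE:
            raise ConfigError(f"unknown true label {truth!r}")
        if pred not in VALID_PRED:
            raise ConfigError(f"unknown predicted label {pred!r}")
        if truth == "AD":
            if pred == "AD":
                tp += 1
            else:  # HS or indeterminate: an error against the true class
                fn += 1
        else:
            if pred == "HS":
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Classification accuracy in percent: 100 * (TP + TN) / total."""
    if cm.total == 0:
        raise ConfigError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def diagnostic_odds_ratio(cm: ConfusionMatrix, haldane: bool = False) -> float:
    """Diagnostic odds ratio TP*TN / (FP*FN).

    With a zero cell in the denominator the DOR is infinite (or undefined,
    0/0 -> NaN); the optional Haldane correction adds 0.5 to every cell
    instead.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    if haldane:
        return (tp + 0.5) * (tn + 0.5) / ((fp + 0.5) * (fn + 0.5))
    if fp * fn == 0:
        return math.inf if tp * tn > 0 else math.nan
    return (tp * tn) / (fp * fn)


def matthews_cc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any marginal is empty."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)
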