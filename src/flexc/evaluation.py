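"""Prediction-quality metrics: per-state Q, overall Q3 and the 2-state
F-measure.

Q_s is per-state recall (residues correctly predicted in observed state s
over residues observed in s) and Q3 is the overall fraction of correctly
classified residues, i.e. the trace of the confusion matrix over its
total.  For two-state comparisons the flexible class is the positive
class: accuracy A = TP/(TP+FP), coverage C = TP/(TP+FN) and
F = 2AC/(A+C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix

from .chains import STATES3


class UndefinedMetricError(ValueError):
    pass


@dataclass
class TwoStateMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float  # A = TP / (TP + FP)
    coverage: float  # C = TP / (TP + FN)
    f_measure: float


@dataclass
class EvalReport:
    states: tuple[str, ...]
    confusion: np.ndarray  # rows = observed, cols = predicted
    q_per_state: dict[str, Optional[float]]
    q3: float
    two_state: Optional[TwoStateMetrics] = None

    @property
    def n_residues(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "confusion": self.confusion.tolist(),
            "q_per_state": self.q_per_state,
            "q3": self.q3,
            "two_state": None if self.two_state is None else vars(self.two_state),
        }


def confusion_and_q(
    observed: Sequence[str],
    predicted: Sequence[str],
    states: Sequence[str] = STATES3,
) -> EvalReport:
    """Confusion matrix plus per-state Q and overall Q3.

    Q_s is None (reported as missing) when state s never occurs in the
    observed vector.
    """
    if len(observed) != len(predicted):
        raise ValueError(
            f"observed ({len(observed)}) and predicted ({len(predicted)}) "
            "lengths differ"
        )
    cm = confusion_matrix(observed, predicted, labels=list(states))
    row_totals = cm.sum(axis=1)
    q = {
        s: (float(cm[i, i] / row_totals[i]) if row_totals[i] > 0 else None)
        for i, s in enumerate(states)
    }
    total = cm.sum()
    q3 = float(np.trace(cm) / total) if total else float("nan")
    return EvalReport(
        states=tuple(states), confusion=cm, q_per_state=q, q3=q3
    )


def f_measure(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Accuracy A, coverage C and F = 2AC/(A+C) for the positive class."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0 and tp + fn == 0:
        raise UndefinedMetricError("no predicted and no observed positives")
    if tp + fp == 0 or tp + fn == 0:
        raise UndefinedMetricError("one of the F-measure denominators is zero")
    a = tp / (tp + fp)
    c = tp / (tp + fn)
    f = 0.0 if a == 0 and c == 0 else 2 * a * c / (a + c)
    return a, c, f


def two_state_report(
    observed: Sequence[str],
    predicted: Sequence[str],
    positive: str = "flexible",
    negative: str = "rigid",
) -> EvalReport:
    """Two-state evaluation with the flexible class as positive."""
    states = (negative, positive)
    report = confusion_and_q(observed, predicted, states=states)
    cm = report.confusion
    tn, fp = int(cm[0, 0]), int(cm[0, 1])
    fn, tp = int(cm[1, 0]), int(cm[1, 1])
    a, c, f = f_measure(tp, fp, fn)
    report.two_state = TwoStateMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn, accuracy=a, coverage=c, f_measure=f
    )
    return report
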