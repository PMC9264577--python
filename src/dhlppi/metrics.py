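"""Confusion-matrix evaluation of predicted interaction sets.

Six summary statistics are computed from TP/FP/FN/TN counts: precision,
recall (= sensitivity for this binary problem), F1, specificity,
accuracy and the Matthews correlation coefficient. Any statistic whose
denominator is zero is reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .hashsearch import PPISet
from .seqio import LabeledPair


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative labels exchanged."""
        return ConfusionCounts(TP=self.TN, FP=self.FN, FN=self.FP, TN=self.TP)


def confusion(
    predicted: PPISet, truth: Iterable[LabeledPair], directed: bool = False
) -> ConfusionCounts:
    """Tally predictions against labeled pairs.

    Evaluation is restricted to the labeled pairs: a truth pair counts as
    predicted-interacting if it appears in the predicted set (in either
    direction by default; exactly as ordered if ``directed``).
    """
    tp = fp = fn = tn = 0
    for pair in truth:
        if directed:
            hit = (pair.id_a, pair.id_b) in predicted
        else:
            hit = predicted.contains_undirected(pair.id_a, pair.id_b)
        if pair.label == 1:
            if hit:
                tp += 1
            else:
                fn += 1
        else:
            if hit:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _ratio(2.0 * precision * recall, precision + recall)


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """The six confusion-matrix statistics; zero denominators yield 0."""
    if c.total < 1:
        raise ValueError("at least one counted pair is required")
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1_score(precision, recall),
        "specificity": _ratio(c.TN, c.TN + c.FP),
        "accuracy": _ratio(c.TP + c.TN, c.total),
        "mcc": _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den),
    }


def format_report(m: dict[str, float], digits: int = 3) -> str:
    """One metric per line, rounded for reporting (3 decimals by default)."""
    return "\n".join(f"{name}\t{value:.{digits}f}" for name, value in m.items())
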