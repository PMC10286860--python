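"""Diagnostic scoring: 2×2 confusion tables, sensitivity/specificity,
and McNemar's test for paired classifiers.

Positive means pathology throughout. A record predicted inconclusive
is treated as false: it counts as predicted negative when the gold
standard is pathological (a missed pathology, fn) and as predicted
positive when the gold standard is healthy (a false alarm, fp). When
category-level predictions are available, naming the *wrong* pathology
for a pathological record also counts as predicted negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

HEALTHY = "healthy"
PATHOLOGICAL = "pathological"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ConfusionTable2x2:
    """TP/FN/FP/TN counts (positive = pathology)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class PairedOutcomes:
    """Per-record correctness of two classifiers on the same records."""

    a_correct: Sequence[bool]
    b_correct: Sequence[bool]

    def __post_init__(self) -> None:
        if len(self.a_correct) != len(self.b_correct):
            raise ValueError("paired outcome lists must have equal length")

    @property
    def discordant(self) -> tuple[int, int]:
        """(b, c): A-correct/B-wrong and A-wrong/B-correct counts."""
        b = sum(a and not bb for a, bb in zip(self.a_correct, self.b_correct))
        c = sum(bb and not a for a, bb in zip(self.a_correct, self.b_correct))
        return b, c


def _is_healthy(v: str) -> bool:
    return v in (HEALTHY, "sinus_rhythm")


def confusion_2x2(
    gold: Sequence[str], pred: Sequence[str]
) -> ConfusionTable2x2:
    """Score predictions against a gold standard.

    ``gold`` entries are "healthy"/"pathological" or category names
    (anything but sinus_rhythm is pathological). ``pred`` entries may
    additionally be "inconclusive". With category-level inputs on both
    sides, a prediction naming a different pathology than the gold
    category scores as predicted negative (a wrong diagnosis is not
    credit for detecting *the* pathology); with binary inputs any
    pathological prediction on a pathological record is a tp.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred must have equal length")
    tp = fn = fp = tn = 0
    for g, p in zip(gold, pred):
        if p == INCONCLUSIVE:
            # inconclusive is treated as false on either gold class
            if _is_healthy(g):
                fp += 1
            else:
                fn += 1
            continue
        if _is_healthy(g):
            if _is_healthy(p):
                tn += 1
            else:
                fp += 1
        else:
            if _is_healthy(p):
                fn += 1
            elif p == PATHOLOGICAL or g == PATHOLOGICAL or p == g:
                tp += 1
            else:  # both are categories and they disagree → wrong pathology
                fn += 1
    return ConfusionTable2x2(tp=tp, fn=fn, fp=fp, tn=tn)


def _pct_1dp(x: float) -> float:
    """Percentage rounded half-up to one decimal (reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def sensitivity(t: ConfusionTable2x2) -> float:
    """100 × tp / (tp + fn), one decimal."""
    if t.tp + t.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no pathological gold records")
    return _pct_1dp(100.0 * t.tp / (t.tp + t.fn))


def specificity(t: ConfusionTable2x2) -> float:
    """100 × tn / (tn + fp), one decimal."""
    if t.tn + t.fp == 0:
        raise ZeroDivisionError("specificity undefined: no healthy gold records")
    return _pct_1dp(100.0 * t.tn / (t.tn + t.fp))


@dataclass(frozen=True)
class McNemarResult:
    statistic: float | None
    p_value: float
    b: int
    c: int
    method: str
    note: str = ""


def mcnemar_test(
    pairs: PairedOutcomes, method: str = "auto"
) -> McNemarResult:
    """McNemar's test on two classifiers' discordant outcomes.

    exact: two-sided binomial tail, p = min(1, 2·P[X ≤ min(b, c)]) with
    X ~ Binomial(b + c, ½). asymptotic: continuity-corrected chi-square
    (|b − c| − 1)² / (b + c) on 1 df. auto: exact when b + c < 25.
    b + c = 0 gives p = 1.0 with a degenerate-case note.
    """
    if method not in ("exact", "asymptotic", "auto"):
        raise ValueError("method must be exact, asymptotic, or auto")
    if len(pairs.a_correct) < 1:
        raise ValueError("need at least one pair")
    b, c = pairs.discordant
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(None, 1.0, b, c, method, note="no discordant pairs")
    if method == "auto":
        method = "exact" if n_disc < 25 else "asymptotic"
    if method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(None, p, b, c, "exact")
    statistic = (abs(b - c) - 1.0) ** 2 / n_disc
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic, p, b, c, "asymptotic")


def paired_outcomes_from_predictions(
    gold: Sequence[str], pred_a: Sequence[str], pred_b: Sequence[str]
) -> PairedOutcomes:
    """Correct/incorrect pairing of two prediction lists vs. one gold.

    Inconclusive predictions are incorrect by the treated-as-false rule.
    """
    if not (len(gold) == len(pred_a) == len(pred_b)):
        raise ValueError("gold and both prediction lists must have equal length")

    def correct(g: str, p: str) -> bool:
        if p == INCONCLUSIVE:
            return False
        return _is_healthy(g) == _is_healthy(p)

    return PairedOutcomes(
        a_correct=[correct(g, p) for g, p in zip(gold, pred_a)],
        b_correct=[correct(g, p) for g, p in zip(gold, pred_b)],
    )
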