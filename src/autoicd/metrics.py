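"""Multi-label evaluation for ICD autocoding.

All scores are micro-averaged: true positives, false positives and false
negatives are pooled over every code instance in every document, then

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * P * R / (P + R)

with the conservative 0/0 -> 0 convention.  Besides the overall score the
module provides the main-code restriction, the top-K-frequent-code
restriction, the per-block-letter breakdown, and the four-way
principal-diagnosis outcome taxonomy with its overall correct rate.

Predictions are :class:`~autoicd.icd.CodeSet` instances; ``None`` marks the
flagged "no principal diagnosis" result a generative decode can produce.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .icd import CodeSet

__all__ = [
    "EvalReport",
    "PdOutcome",
    "f_measure",
    "micro_prf",
    "main_code_f",
    "topk_f",
    "per_block_f",
    "pd_outcome",
    "overall_correct_rate",
]

Prediction = Optional[CodeSet]


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalReport:
    """Pooled micro counts and the derived precision/recall/F."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }


def _check_aligned(preds: Sequence, golds: Sequence) -> None:
    if len(preds) != len(golds):
        raise ValueError(
            f"prediction/gold length mismatch: {len(preds)} vs {len(golds)}"
        )


def _pred_set(pred: Prediction) -> frozenset[str]:
    return frozenset() if pred is None else pred.all_codes()


def _count_sets(
    pred_sets: Sequence[frozenset[str]], gold_sets: Sequence[frozenset[str]]
) -> EvalReport:
    tp = fp = fn = 0
    for p, g in zip(pred_sets, gold_sets):
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    return EvalReport(tp=tp, fp=fp, fn=fn)


def micro_prf(
    preds: Sequence[Prediction], golds: Sequence[CodeSet]
) -> EvalReport:
    """Pooled precision/recall/F over full predicted vs gold code sets."""
    _check_aligned(preds, golds)
    return _count_sets(
        [_pred_set(p) for p in preds], [g.all_codes() for g in golds]
    )


def main_code_f(
    preds: Sequence[Prediction], golds: Sequence[CodeSet]
) -> EvalReport:
    """Micro P/R/F restricted to the singleton main-code sets.

    A flagged no-principal-diagnosis prediction contributes a false negative
    only.
    """
    _check_aligned(preds, golds)
    pred_sets = [
        frozenset() if p is None else frozenset({p.main_code.code}) for p in preds
    ]
    gold_sets = [frozenset({g.main_code.code}) for g in golds]
    return _count_sets(pred_sets, gold_sets)


def topk_codes(freq_table: Mapping[str, int], k: int) -> frozenset[str]:
    """The k most frequent codes; ties broken lexicographically."""
    ranked = sorted(freq_table, key=lambda c: (-freq_table[c], c))
    return frozenset(ranked[:k])


def topk_f(
    preds: Sequence[Prediction],
    golds: Sequence[CodeSet],
    k: int,
    freq_table: Mapping[str, int],
) -> EvalReport:
    """Micro P/R/F after intersecting both sides with the top-k frequent codes."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_aligned(preds, golds)
    top = topk_codes(freq_table, k)
    return _count_sets(
        [_pred_set(p) & top for p in preds],
        [g.all_codes() & top for g in golds],
    )


def per_block_f(
    preds: Sequence[Prediction], golds: Sequence[CodeSet]
) -> dict[str, EvalReport]:
    """Micro P/R/F per block letter (first character of the code).

    Letters with no gold and no predicted instances are omitted.
    """
    _check_aligned(preds, golds)
    letters = sorted(
        {c[0] for p in preds for c in _pred_set(p)}
        | {c[0] for g in golds for c in g.all_codes()}
    )
    out = {}
    for letter in letters:
        out[letter] = _count_sets(
            [{c for c in _pred_set(p) if c[0] == letter} for p in preds],
            [{c for c in g.all_codes() if c[0] == letter} for g in golds],
        )
    return out


class PdOutcome(enum.Enum):
    """Four-way agreement taxonomy for the principal diagnosis."""

    ALL_CORRECT = "all_correct"
    PD_CORRECT_SECONDARY_MISMATCH = "pd_correct_secondary_mismatch"
    NO_PRINCIPAL_DIAGNOSIS = "no_principal_diagnosis"
    ALL_INCORRECT = "all_incorrect"


def pd_outcome(pred: Prediction, gold: CodeSet) -> PdOutcome:
    """Classify one case against the human coder's codes.

    Precedence: identical full sets with equal mains -> ALL_CORRECT; equal
    mains otherwise -> PD_CORRECT_SECONDARY_MISMATCH; differing (or absent)
    mains with overlapping full sets -> NO_PRINCIPAL_DIAGNOSIS; disjoint
    full sets -> ALL_INCORRECT.
    """
    pred_all = _pred_set(pred)
    gold_all = gold.all_codes()
    mains_equal = pred is not None and pred.main_code.code == gold.main_code.code
    if mains_equal and pred_all == gold_all:
        return PdOutcome.ALL_CORRECT
    if mains_equal:
        return PdOutcome.PD_CORRECT_SECONDARY_MISMATCH
    if pred_all & gold_all:
        return PdOutcome.NO_PRINCIPAL_DIAGNOSIS
    return PdOutcome.ALL_INCORRECT


def overall_correct_rate(outcomes: Sequence[PdOutcome]) -> float:
    """Fraction of cases where the principal diagnosis was right.

    Counts both ALL_CORRECT and PD_CORRECT_SECONDARY_MISMATCH.
    """
    if not outcomes:
        raise ValueError("empty outcome list")
    good = sum(
        1
        for o in outcomes
        if o in (PdOutcome.ALL_CORRECT, PdOutcome.PD_CORRECT_SECONDARY_MISMATCH)
    )
    return good / len(outcomes)
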