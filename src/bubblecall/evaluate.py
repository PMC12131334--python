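"""Precision/recall scoring of called bubbles against planted truth."""

from __future__ import annotations

from dataclasses import dataclass

from .bubbles import canonical_pair
from .simulate import PlantedTruth


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    n_called: int
    n_true: int
    n_matched: int


def evaluate(calls: set[tuple[str, str]], truth: PlantedTruth) -> EvalReport:
    """Match canonical call pairs against truth context pairs.

    A call matches a truth SNP iff its strand-canonical sequence pair
    equals the truth context pair (order-insensitive); each truth SNP is
    matched at most once.  Precision over an empty call set is 0 by
    convention.
    """
    canon_calls = {canonical_pair(a, b) for a, b in calls}
    remaining: dict[tuple[str, str], int] = {}
    for cr, ca in truth.contexts:
        key = canonical_pair(cr, ca)
        remaining[key] = remaining.get(key, 0) + 1
    matched = 0
    for pair in sorted(canon_calls):
        if remaining.get(pair, 0) > 0:
            remaining[pair] -= 1
            matched += 1
    n_called = len(canon_calls)
    n_true = len(truth.contexts)
    precision = matched / n_called if n_called else 0.0
    recall = matched / n_true if n_true else 0.0
    return EvalReport(precision, recall, n_called, n_true, matched)
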