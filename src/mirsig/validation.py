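"""Validation statistics: confusion-matrix metrics, read support, TPM and
relative qRT-PCR expression.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN); a metric with a zero denominator is reported as None
(undefined), never as 0. A prediction is "confirmed" by a small-RNA
library when at least one full-length read matches its mature sequence;
expression is reported as reads per million (TPM) of the cleaned library
total, and qRT-PCR expression relative to a reference gene as 2^-dCT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import CollapsedRead

__all__ = [
    "ConfusionCounts",
    "ExpressionRecord",
    "confusion_metrics",
    "match_reads",
    "tpm",
    "relative_expression",
    "evaluate_against_known",
    "expression_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class ExpressionRecord:
    mirna_id: str
    read_count: int
    tpm: float
    ct: float | None = None
    rel_expr: float | None = None


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV and NPV from confusion counts."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def match_reads(
    mature_seqs: Mapping[str, str],
    reads: Sequence[CollapsedRead],
    max_mismatches: int = 0,
) -> dict[str, int]:
    """Summed read count per prediction id over full-length read matches.

    A read supports a mature when it has the same length and at most
    ``max_mismatches`` substitutions (exact identity by default). Reads
    are expected to be length-cleaned already (>= 14 nt).
    """
    by_len: dict[int, list[CollapsedRead]] = {}
    for r in reads:
        by_len.setdefault(len(r.seq), []).append(r)
    counts: dict[str, int] = {}
    for pid, mat in mature_seqs.items():
        total = 0
        for r in by_len.get(len(mat), ()):
            if max_mismatches == 0:
                if r.seq == mat:
                    total += r.count
            elif _mismatches(r.seq, mat) <= max_mismatches:
                total += r.count
        counts[pid] = total
    return counts


def tpm(read_count: int, total_reads: int) -> float:
    """Reads per million of the library total."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return read_count / total_reads * 1e6


def relative_expression(ct_mirna: float, ct_reference: float) -> float:
    """qRT-PCR expression relative to a reference gene: 2^-(CTmiR - CTref)."""
    return 2.0 ** (-(ct_mirna - ct_reference))


def evaluate_against_known(
    predicted: Iterable[str],
    known: Iterable[str],
    candidate_universe: Iterable[str] = (),
    end_offset_slack: int = 0,
) -> ConfusionCounts:
    """Confusion counts of predicted mature sequences against a known set.

    A prediction matches a known mature when the sequences are identical,
    or — with ``end_offset_slack`` > 0 — when one is a substring of the
    other with total overhang at most the slack (a small 5'/3' end offset).
    TN counts universe members that are neither predicted nor known.
    """
    pred = sorted(set(predicted))
    knw = set(known)

    def matches(p: str) -> bool:
        if p in knw:
            return True
        if end_offset_slack > 0:
            for k in knw:
                short, long_ = (p, k) if len(p) <= len(k) else (k, p)
                if len(long_) - len(short) <= end_offset_slack and short in long_:
                    return True
        return False

    matched_preds = {p for p in pred if matches(p)}
    tp = len(matched_preds)
    fp = len(pred) - tp
    # known matures not recovered by any prediction
    def known_hit(k: str) -> bool:
        if k in matched_preds:
            return True
        if end_offset_slack > 0:
            for p in matched_preds:
                short, long_ = (p, k) if len(p) <= len(k) else (k, p)
                if len(long_) - len(short) <= end_offset_slack and short in long_:
                    return True
        return False

    fn = sum(1 for k in knw if not known_hit(k))
    universe = set(candidate_universe)
    tn = len(universe - set(pred) - knw)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def expression_report(
    mature_seqs: Mapping[str, str],
    reads: Sequence[CollapsedRead],
    total_reads: int | None = None,
    max_mismatches: int = 0,
) -> pd.DataFrame:
    """Per-prediction read support and TPM (confirmed = read_count >= 1).

    ``total_reads`` defaults to the summed counts of the cleaned library.
    """
    if total_reads is None:
        total_reads = sum(r.count for r in reads)
    counts = match_reads(mature_seqs, reads, max_mismatches=max_mismatches)
    rows = [
        {
            "mirna_id": pid,
            "read_count": n,
            "tpm": tpm(n, total_reads) if total_reads > 0 else 0.0,
            "confirmed": n >= 1,
        }
        for pid, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "read_count", "tpm", "confirmed"])
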