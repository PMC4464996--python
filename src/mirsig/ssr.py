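"""Simple sequence repeat (SSR) signatures of miRNA families.

A family's signature is the k-mer motif (k = 3 by default) present in
every member whose average density R is maximal, where

    R = occurrences / L * 100    (signatures per 100 nt).

Occurrences are counted at every (overlapping) start position. For
single-member families the motif with maximum R in that one sequence is
taken. A catalog maps each family to its signature; families whose best
shared motif falls below the density threshold (average R >= 2.5 by
default) are recorded as signature-less.

An optional ``tandem_only`` mode restricts counting to motif occurrences
inside perfect tandem runs of at least two units, for sensitivity analysis
of the occurrence-counting reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .seqio import SequenceRecord

__all__ = [
    "SSRSignature",
    "SignatureCatalog",
    "count_motif",
    "r_value",
    "family_signature",
    "build_catalog",
    "signature_distribution",
]

_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class SSRSignature:
    family: str
    motif: str
    avg_r: float
    n_members: int


@dataclass
class SignatureCatalog:
    """Per-family SSR signatures plus the families that yielded none."""

    signatures: dict[str, SSRSignature]
    window: int = 3
    min_avg_r: float = 2.5
    unassigned: list[str] | None = None

    def __post_init__(self) -> None:
        if self.unassigned is None:
            self.unassigned = []

    def get(self, family: str) -> SSRSignature | None:
        return self.signatures.get(family)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": s.family, "motif": s.motif, "avg_r": s.avg_r, "n_members": s.n_members}
            for s in sorted(self.signatures.values(), key=lambda s: s.family)
        ]
        return pd.DataFrame(rows, columns=["family", "motif", "avg_r", "n_members"])


def _check_motif(motif: str) -> None:
    if not motif or set(motif) - _ALPHABET:
        raise ValueError(f"invalid motif {motif!r}: must be non-empty over A,C,G,U")


def count_motif(seq: str, motif: str, tandem_only: bool = False) -> int:
    """Number of (overlapping) exact occurrences of ``motif`` in ``seq``.

    With ``tandem_only``, only occurrences lying inside a perfect tandem
    run of >= 2 consecutive units are counted.
    """
    _check_motif(motif)
    seq = seq.upper().replace("T", "U")
    k = len(motif)
    positions = [i for i in range(len(seq) - k + 1) if seq[i : i + k] == motif]
    if not tandem_only:
        return len(positions)
    pos_set = set(positions)
    return sum(1 for i in positions if (i + k in pos_set) or (i - k in pos_set))


def r_value(seq: str, motif: str, tandem_only: bool = False) -> float:
    """Motif density per 100 nt: count / L * 100."""
    return count_motif(seq, motif, tandem_only=tandem_only) / len(seq) * 100.0


def _member_seqs(members: Sequence[SequenceRecord | str]) -> list[str]:
    return [
        (m.seq if isinstance(m, SequenceRecord) else m).upper().replace("T", "U")
        for m in members
    ]


def family_signature(
    members: Sequence[SequenceRecord | str],
    window: int = 3,
    min_avg_r: float = 2.5,
    enforce_threshold: bool = True,
    tandem_only: bool = False,
    family: str = "",
) -> SSRSignature | None:
    """The conserved SSR signature of one family, or None.

    Multi-member families: candidate motifs must occur (count >= 1) in
    every member; the winner maximizes the average R over members, ties
    broken lexicographically. Single-member families: the motif with
    maximum R in that sequence. When ``enforce_threshold`` is set the
    signature is returned only if its average R >= ``min_avg_r``.
    """
    if not members:
        raise ValueError("family must have at least one member")
    seqs = _member_seqs(members)
    # Candidate motifs: k-mers of the first member shared by all others
    # (exhaustive over the 4^k alphabet is equivalent but slower).
    first_kmers = {seqs[0][i : i + window] for i in range(len(seqs[0]) - window + 1)}
    first_kmers = {m for m in first_kmers if not set(m) - _ALPHABET}
    shared = [
        m for m in first_kmers
        if all(count_motif(s, m, tandem_only=tandem_only) >= 1 for s in seqs[1:])
    ]
    if tandem_only:
        shared = [m for m in shared if count_motif(seqs[0], m, tandem_only=True) >= 1]
    if not shared:
        return None

    def avg_r(m: str) -> float:
        return sum(r_value(s, m, tandem_only=tandem_only) for s in seqs) / len(seqs)

    # maximize average R; ties broken toward the lexicographically smallest
    # motif (sort ascending, take max of (avg_r, reversed-name) equivalent)
    motif = min(sorted(shared), key=lambda m: (-avg_r(m), m))
    best_avg = avg_r(motif)
    if enforce_threshold and best_avg < min_avg_r:
        return None
    return SSRSignature(family=family, motif=motif, avg_r=best_avg, n_members=len(seqs))


def build_catalog(
    families: Mapping[str, Sequence[SequenceRecord | str]],
    window: int = 3,
    min_avg_r: float = 2.5,
    enforce_threshold: bool = True,
    tandem_only: bool = False,
) -> SignatureCatalog:
    """Build the per-family signature catalog."""
    signatures: dict[str, SSRSignature] = {}
    unassigned: list[str] = []
    for fam in sorted(families):
        sig = family_signature(
            families[fam],
            window=window,
            min_avg_r=min_avg_r,
            enforce_threshold=enforce_threshold,
            tandem_only=tandem_only,
            family=fam,
        )
        if sig is None:
            unassigned.append(fam)
        else:
            signatures[fam] = sig
    return SignatureCatalog(
        signatures=signatures, window=window, min_avg_r=min_avg_r, unassigned=unassigned
    )


def signature_distribution(catalog: SignatureCatalog) -> pd.DataFrame:
    """Percentage of signature-bearing families carrying each motif.

    Percentages sum to 100 over the families that have a signature.
    """
    if not catalog.signatures:
        raise ValueError("empty catalog")
    n = len(catalog.signatures)
    counts: dict[str, int] = {}
    for sig in catalog.signatures.values():
        counts[sig.motif] = counts.get(sig.motif, 0) + 1
    rows = [
        {"motif": m, "n_families": c, "pct_families": c / n * 100.0}
        for m, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["motif", "n_families", "pct_families"])
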