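"""Homology scanning, candidate window enumeration, and coding exclusion.

Mature miRNAs are short (~15-24 nt), so homologs are modeled as ungapped
full-query alignments: a hit is any subject placement, on either strand,
that contains at least one exact ``word_size`` seed and accumulates at
most ``max_mismatches`` substitutions over the whole query. With word
size 7 and the permissive e-value the original protocol used, the seed
and the mismatch bound are the only operative filters, so no alignment
statistics are computed; externally computed tabular hits can be ingested
via :func:`mirsig.seqio.read_blast_tab` instead.

Candidate precursor windows of every length in [min_len, max_len] that
contain the full hit are enumerated around each hit; candidates whose
six-frame translation matches a supplied protein at >= 80% identity over
>= 20 aligned residues are excluded as coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .seqio import SequenceRecord, revcomp, to_rna

__all__ = [
    "HomologyHit",
    "CandidateWindow",
    "scan_homologs",
    "enumerate_windows",
    "coding_filter",
]


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped full-query match of a known mature miRNA on a subject."""

    query_id: str
    subject_id: str
    subject_start: int  # 0-based half-open on the + strand of the subject
    subject_end: int
    strand: str  # '+' or '-'
    mismatches: int
    query_span: tuple[int, int] = (0, 0)
    query_coverage: float = 1.0

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)

    def __len__(self) -> int:
        return self.subject_end - self.subject_start


@dataclass
class CandidateWindow:
    """A precursor-sized window around a hit, oriented with the mature strand.

    ``seq`` is the window sequence in U-space, reverse-complemented for
    minus-strand hits; ``mature_span`` is the hit's location within that
    oriented sequence. ``window_start``/``window_end`` stay in subject
    (+ strand) coordinates.
    """

    subject_id: str
    window_start: int
    window_end: int
    strand: str
    seq: str
    hit: HomologyHit
    mature_span: tuple[int, int]

    @property
    def id(self) -> str:
        # 1-based inclusive coordinates at the format boundary
        return f"{self.subject_id}:{self.window_start + 1}-{self.window_end}:{self.strand}"

    def __len__(self) -> int:
        return self.window_end - self.window_start


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def scan_homologs(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    word_size: int = 7,
    max_mismatches: int = 3,
) -> list[HomologyHit]:
    """Seed-and-extend scan of subjects against mature miRNA queries.

    Reports every subject placement (both strands) covering the full query
    with at least one exact ``word_size`` match and total mismatches
    <= ``max_mismatches``; duplicates by (query, subject, span, strand) are
    collapsed. Queries shorter than ``word_size`` are skipped with a
    warning.
    """
    seeds: dict[str, list[tuple[int, int]]] = {}
    qseqs: list[str] = []
    for qi, q in enumerate(queries):
        qseq = to_rna(q.seq)
        qseqs.append(qseq)
        if len(qseq) < word_size:
            warnings.warn(f"query {q.id!r} shorter than word size {word_size}; skipped")
            continue
        for off in range(len(qseq) - word_size + 1):
            seeds.setdefault(qseq[off : off + word_size], []).append((qi, off))

    hits: list[HomologyHit] = []
    for subj in subjects:
        n = len(subj.seq)
        for strand in "+-":
            s = to_rna(subj.seq) if strand == "+" else revcomp(subj.seq)
            checked: set[tuple[int, int]] = set()
            for pos in range(n - word_size + 1):
                for qi, off in seeds.get(s[pos : pos + word_size], ()):
                    start = pos - off
                    qlen = len(qseqs[qi])
                    if start < 0 or start + qlen > n:
                        continue
                    key = (qi, start)
                    if key in checked:
                        continue
                    checked.add(key)
                    mm = _hamming(qseqs[qi], s[start : start + qlen])
                    if mm <= max_mismatches:
                        if strand == "+":
                            span = (start, start + qlen)
                        else:
                            span = (n - start - qlen, n - start)
                        hits.append(
                            HomologyHit(
                                query_id=queries[qi].id,
                                subject_id=subj.id,
                                subject_start=span[0],
                                subject_end=span[1],
                                strand=strand,
                                mismatches=mm,
                                query_span=(0, qlen),
                            )
                        )
    return hits


def enumerate_windows(
    subject: SequenceRecord,
    hit: HomologyHit,
    min_len: int = 55,
    max_len: int = 505,
    stride: int = 1,
) -> list[CandidateWindow]:
    """All windows of lengths in [min_len, max_len] containing the full hit.

    Both the window length and the placement offset are stepped by
    ``stride`` (1 = exhaustive). Windows never extend past the subject
    bounds; the mature span is recomputed in each window's oriented
    coordinates.
    """
    n = len(subject.seq)
    h0, h1 = hit.subject_start, hit.subject_end
    if not (0 <= h0 < h1 <= n):
        raise ValueError("hit span outside subject bounds")
    out: list[CandidateWindow] = []
    subj_rna = to_rna(subject.seq)
    for length in range(min_len, max_len + 1, stride):
        if length > n or length < (h1 - h0):
            continue
        lo = max(0, h1 - length)
        hi = min(h0, n - length)
        for w in range(lo, hi + 1, stride):
            wseq = subj_rna[w : w + length]
            if hit.strand == "+":
                mspan = (h0 - w, h1 - w)
            else:
                wseq = revcomp(wseq)
                mspan = (w + length - h1, w + length - h0)
            out.append(
                CandidateWindow(
                    subject_id=subject.id,
                    window_start=w,
                    window_end=w + length,
                    strand=hit.strand,
                    seq=wseq,
                    hit=hit,
                    mature_span=mspan,
                )
            )
    return out


def _six_frames(seq_rna: str) -> list[str]:
    dna = Seq(seq_rna.replace("U", "T"))
    frames = []
    for s in (dna, dna.reverse_complement()):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                frames.append(str(sub.translate()))
    return frames


def _has_protein_match(frame: str, protein: str, min_identity_pct: float, min_aln_aa: int) -> bool:
    # ungapped diagonal scan: any min_aln_aa-residue window at >= identity
    need = min_identity_pct / 100.0 * min_aln_aa
    lf, lp = len(frame), len(protein)
    if lf < min_aln_aa or lp < min_aln_aa:
        return False
    for d in range(-(lf - min_aln_aa), lp - min_aln_aa + 1):
        # frame[i] aligned to protein[i + d]
        i0 = max(0, -d)
        i1 = min(lf, lp - d)
        if i1 - i0 < min_aln_aa:
            continue
        matches = [1 if frame[i] == protein[i + d] and frame[i] != "*" else 0
                   for i in range(i0, i1)]
        run = sum(matches[:min_aln_aa])
        if run >= need:
            return True
        for k in range(min_aln_aa, len(matches)):
            run += matches[k] - matches[k - min_aln_aa]
            if run >= need:
                return True
    return False


def coding_segments(
    subject_seq: str,
    proteins: Sequence[SequenceRecord],
    min_identity_pct: float = 80.0,
    min_aln_aa: int = 20,
) -> list[tuple[int, int]]:
    """Nucleotide spans (0-based half-open, + strand coords) of qualifying
    translated matches anywhere in a subject.

    Every ``min_aln_aa``-residue ungapped diagonal window at identity
    >= ``min_identity_pct``, in any of the six frames, is reported as the
    nucleotide span it covers. A candidate window contains a qualifying
    translated alignment iff it contains one of these spans, so scanning
    the subject once is equivalent to scanning every candidate window.
    """
    from Bio.Seq import Seq

    n = len(subject_seq)
    dna = Seq(subject_seq.upper().replace("U", "T"))
    need = min_identity_pct / 100.0 * min_aln_aa
    segments: list[tuple[int, int]] = []
    for rc in (False, True):
        s = dna.reverse_complement() if rc else dna
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3 * min_aln_aa:
                continue
            frame = str(sub.translate())
            for prot in proteins:
                p = prot.seq.upper()
                lf, lp = len(frame), len(p)
                if lp < min_aln_aa:
                    continue
                for d in range(-(lf - min_aln_aa), lp - min_aln_aa + 1):
                    i0 = max(0, -d)
                    i1 = min(lf, lp - d)
                    if i1 - i0 < min_aln_aa:
                        continue
                    matches = [
                        1 if frame[i] == p[i + d] and frame[i] != "*" else 0
                        for i in range(i0, i1)
                    ]
                    run = sum(matches[:min_aln_aa])
                    for w0 in range(0, len(matches) - min_aln_aa + 1):
                        if w0 > 0:
                            run += matches[w0 + min_aln_aa - 1] - matches[w0 - 1]
                        if run >= need:
                            aa_start = i0 + w0
                            nt_start = off + 3 * aa_start
                            nt_end = nt_start + 3 * min_aln_aa
                            if rc:
                                nt_start, nt_end = n - nt_end, n - nt_start
                            segments.append((nt_start, nt_end))
    return sorted(set(segments))


def coding_filter(
    candidates: Sequence[CandidateWindow],
    proteins: Sequence[SequenceRecord],
    min_identity_pct: float = 80.0,
    min_aln_aa: int = 20,
    rejected_ids: Iterable[str] | None = None,
) -> tuple[list[CandidateWindow], list[CandidateWindow]]:
    """Split candidates into (kept, rejected) by translated similarity.

    A candidate is rejected iff any of its six reading-frame translations
    contains an ungapped alignment to any supplied protein at identity
    >= ``min_identity_pct`` over >= ``min_aln_aa`` residues. Alternatively,
    ``rejected_ids`` (e.g. query ids from a precomputed translated-search
    tabular file, already thresholded) can name rejects directly.
    """
    if rejected_ids is not None:
        rej = set(rejected_ids)
        kept = [c for c in candidates if c.id not in rej]
        rejected = [c for c in candidates if c.id in rej]
        return kept, rejected
    pseqs = [p.seq.upper() for p in proteins]
    kept, rejected = [], []
    frame_cache: dict[str, bool] = {}
    for c in candidates:
        verdict = frame_cache.get(c.seq)
        if verdict is None:
            verdict = any(
                _has_protein_match(f, p, min_identity_pct, min_aln_aa)
                for f in _six_frames(c.seq)
                for p in pseqs
            )
            frame_cache[c.seq] = verdict
        (rejected if verdict else kept).append(c)
    return kept, rejected
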