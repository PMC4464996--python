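"""Readers/writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the
conventions the prediction pipeline relies on: case/alphabet normalization
(T->U for RNA-role sequences), optional removal of redundant sequences,
miRBase-style name parsing (which defines miRNA family membership), the
collapsed small-RNA read dialect, and ingestion of 12-column BLAST tabular
hit files.

All internal coordinates are 0-based half-open; 1-based inclusive appears
only at format boundaries (BLAST tabular input, FASTA description output).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "MiRNAName",
    "CollapsedRead",
    "read_fasta",
    "write_fasta",
    "parse_mirna_name",
    "read_collapsed_reads",
    "read_blast_tab",
    "to_rna",
    "to_dna",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in U-space (accepts T or U input)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (EST/GSS subject, precursor or mature miRNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MiRNAName:
    """Parsed miRBase-style name, e.g. pvu-miR399a.

    ``family`` is the canonical family id ("MIR" + digits); ``variant`` is
    the residual suffix (letters, -3p/-5p tags ...), possibly empty.
    ``precursor`` records whether the name used the MIR (precursor) or miR
    (mature) capitalization, so formatting round-trips exactly.
    """

    species_prefix: str
    family: str
    variant: str = ""
    precursor: bool = False

    def format(self) -> str:
        token = "MIR" if self.precursor else "miR"
        return f"{self.species_prefix}-{token}{self.family[3:]}{self.variant}"


_NAME_RE = re.compile(r"^([A-Za-z0-9]+)-(miR|MIR)(\d+)(.*)$")


def parse_mirna_name(name: str) -> MiRNAName:
    """Parse ``<prefix>-miR<digits><suffix>`` (or MIR for precursors).

    Raises ValueError naming the offending id on an unparseable name.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse miRNA name: {name!r}")
    prefix, token, digits, suffix = m.groups()
    return MiRNAName(
        species_prefix=prefix,
        family=f"MIR{digits}",
        variant=suffix,
        precursor=(token == "MIR"),
    )


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA read sequence with its abundance."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if not self.seq:
            raise ValueError("empty read sequence")


def _open(path_or_handle) -> TextIO:
    if hasattr(path_or_handle, "read"):
        return path_or_handle
    return open(path_or_handle, "r")


def _validate_fasta_head(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"malformed FASTA: line {lineno} does not start a record "
                f"(expected '>'): {line[:40]!r}"
            )
        return


def read_fasta(
    path_or_handle,
    dedupe: bool = False,
    rna: bool = False,
) -> list[SequenceRecord]:
    """Read FASTA records, preserving order.

    With ``dedupe=True``, redundant sequences (exact duplicates after case
    normalization) are collapsed to the first occurrence. With ``rna=True``
    sequences are converted to U-space.
    """
    handle = _open(path_or_handle)
    text = handle.read()
    if hasattr(path_or_handle, "read") is False:
        handle.close()
    if not text.strip():
        return []
    _validate_fasta_head(text)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if rna:
            seq = to_rna(seq)
        if dedupe:
            key = to_rna(seq)
            if key in seen:
                continue
            seen.add(key)
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path_or_handle, width: int = 70) -> None:
    close = False
    if hasattr(path_or_handle, "write"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle, "w")
        close = True
    try:
        for rec in records:
            header = rec.description if rec.description and rec.description != rec.id else rec.id
            handle.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


_COUNT_RE = re.compile(r"[_-]x(\d+)$")


def read_collapsed_reads(
    path_or_handle,
    min_len: int = 14,
    fmt: str | None = None,
) -> list[CollapsedRead]:
    """Read a small-RNA library as unique reads with counts.

    Two dialects are accepted: collapsed FASTA with counts encoded in the
    header as ``<id>_x<count>`` (the common collapser convention), and plain
    FASTQ, in which case identical sequences are accumulated on the fly.
    Reads shorter than ``min_len`` nucleotides are removed (the cleaning
    step applied before expression analysis); counts of retained reads are
    conserved.
    """
    handle = _open(path_or_handle)
    text = handle.read()
    if not hasattr(path_or_handle, "read"):
        handle.close()
    if not text.strip():
        return []
    if fmt is None:
        fmt = "fastq" if text.lstrip().startswith("@") else "fasta"

    counts: dict[str, int] = {}
    order: list[str] = []

    def add(seq: str, n: int) -> None:
        seq = to_rna(seq)
        if seq not in counts:
            counts[seq] = 0
            order.append(seq)
        counts[seq] += n

    if fmt == "fasta":
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            m = _COUNT_RE.search(rec.id)
            if m is None:
                warnings.warn(
                    f"collapsed-read header {rec.id!r} has no _x<count> suffix; "
                    "assuming count 1"
                )
                n = 1
            else:
                n = int(m.group(1))
            add(str(rec.seq), n)
    else:
        for rec in SeqIO.parse(io.StringIO(text), "fastq"):
            add(str(rec.seq), 1)

    return [CollapsedRead(seq=s, count=counts[s]) for s in order if len(s) >= min_len]


def read_blast_tab(path_or_handle) -> list:
    """Read 12-column BLAST tabular hits into :class:`~mirsig.homology.HomologyHit`.

    Subject coordinates (1-based inclusive, possibly reversed on the minus
    strand) are converted to the internal 0-based half-open convention;
    strand is inferred from the subject coordinate order.
    """
    from .homology import HomologyHit

    handle = _open(path_or_handle)
    text = handle.read()
    if not hasattr(path_or_handle, "read"):
        handle.close()
    hits = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 12:
            raise ValueError(
                f"BLAST tabular line {lineno}: expected 12 columns, got {len(cols)}"
            )
        qid, sid = cols[0], cols[1]
        mismatches = int(cols[4])
        qstart, qend = int(cols[6]), int(cols[7])
        sstart, send = int(cols[8]), int(cols[9])
        if sstart <= send:
            strand = "+"
            span = (sstart - 1, send)
        else:
            strand = "-"
            span = (send - 1, sstart)
        hits.append(
            HomologyHit(
                query_id=qid,
                subject_id=sid,
                subject_start=span[0],
                subject_end=span[1],
                strand=strand,
                mismatches=mismatches,
                query_span=(qstart - 1, qend),
            )
        )
    return hits
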