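"""End-to-end precursor prediction: the seven-criterion filter and its
orchestration.

A candidate precursor window around a homology hit is accepted when all
seven criteria hold:

1. it folds into a stem-loop with negative free energy and MFEI at or
   above the cutoff;
2. the mature sequence lies on one arm of the hairpin, outside the
   terminal loop;
3. the mature has fewer than 6 mismatches against its miRNA* partner;
4. the miRNA* has no loop or break (every paired position inside the star
   span pairs back into the mature);
5. AU content lies inside the acceptance range;
6. NQ, ND and Npb lie inside their acceptance bounds;
7. the query family has an SSR signature and the window carries it at
   density R >= 2.5.

Among the windows of one hit that pass all seven, the one maximizing
MFEI, then R, then (for determinism) the shortest and leftmost window is
selected; the mature is the window segment aligned to the query, and
predictions are deduplicated at the mature-sequence level within each
family before miRBase-style names are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .descriptors import CutoffSet, DescriptorSet, check_descriptors, compute_descriptors
from .folding import BuiltinBackend, FoldingBackend, analyze_duplex
from .homology import (
    CandidateWindow,
    HomologyHit,
    coding_segments,
    enumerate_windows,
    scan_homologs,
)
from .seqio import SequenceRecord, parse_mirna_name
from .ssr import SignatureCatalog, r_value

__all__ = [
    "CriteriaReport",
    "Prediction",
    "TargetParamProfile",
    "PipelineConfig",
    "StageReport",
    "apply_criteria",
    "select_best",
    "extract_mature",
    "name_predictions",
    "psrnatarget_params",
    "run_pipeline",
    "predictions_frame",
]


@dataclass
class CriteriaReport:
    """Outcome of the seven acceptance criteria for one candidate window."""

    c1_hairpin_mfei: bool
    c2_mature_one_arm: bool
    c3_duplex_mismatches: bool
    c4_star_intact: bool
    c5_au_content: bool
    c6_folding_measures: bool
    c7_ssr_signature: bool
    reason: str = ""

    @property
    def overall(self) -> bool:
        return (
            self.c1_hairpin_mfei
            and self.c2_mature_one_arm
            and self.c3_duplex_mismatches
            and self.c4_star_intact
            and self.c5_au_content
            and self.c6_folding_measures
            and self.c7_ssr_signature
        )

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.c1_hairpin_mfei,
            self.c2_mature_one_arm,
            self.c3_duplex_mismatches,
            self.c4_star_intact,
            self.c5_au_content,
            self.c6_folding_measures,
            self.c7_ssr_signature,
        )


@dataclass
class Prediction:
    """An accepted precursor with its extracted mature miRNA."""

    precursor: CandidateWindow
    mature_seq: str
    mature_span: tuple[int, int]
    family: str
    descriptors: DescriptorSet
    r_signature: float
    report: CriteriaReport
    name: str = ""
    provenance: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TargetParamProfile:
    """Submission-ready target-prediction parameter block for one miRNA length."""

    mirna_len: int
    hpsize: int
    central_mismatch: tuple[int, int]
    max_expectation: float = 2.0
    max_upe: float = 25.0
    flank_up: int = 17
    flank_down: int = 13


_CENTRAL_MISMATCH = {
    14: (6, 8), 15: (7, 8), 16: (7, 9), 17: (8, 9), 18: (8, 10), 19: (9, 10),
    20: (9, 11), 21: (10, 11), 22: (10, 12), 23: (11, 12), 24: (11, 13),
}


def psrnatarget_params(mirna_len: int) -> TargetParamProfile:
    """Length-adjusted target-prediction parameters (hpsize = miRNA length,
    central-mismatch range per the published mapping)."""
    if mirna_len not in _CENTRAL_MISMATCH:
        raise ValueError(f"miRNA length {mirna_len} outside supported range 14-24")
    return TargetParamProfile(
        mirna_len=mirna_len,
        hpsize=mirna_len,
        central_mismatch=_CENTRAL_MISMATCH[mirna_len],
    )


def apply_criteria(
    window: CandidateWindow,
    cutoffs: CutoffSet,
    catalog: SignatureCatalog,
    family: str,
    backend: FoldingBackend | None = None,
    r_min: float = 2.5,
) -> tuple[CriteriaReport, DescriptorSet, float]:
    """Evaluate the seven criteria for one candidate window.

    Returns the report together with the window's descriptors and its
    signature density R (0 when the family has no signature).
    """
    backend = backend or BuiltinBackend()
    profile = backend.fold(window.seq)
    desc = compute_descriptors(window.seq, profile)
    checks = check_descriptors(desc, cutoffs)
    duplex = analyze_duplex(profile, window.mature_span)

    c1 = profile.mfe < 0 and checks["mfei"]
    c2 = duplex.same_arm and not duplex.overlaps_loop
    c3 = duplex.mismatches < 6
    c4 = duplex.star_contiguous
    c5 = checks["au_pct"]
    c6 = checks["nq"] and checks["nd"] and checks["npb"]
    sig = catalog.get(family)
    if sig is None:
        c7 = False
        r_sig = 0.0
        reason = f"family {family} has no SSR signature"
    else:
        r_sig = r_value(window.seq, sig.motif)
        c7 = r_sig >= r_min
        reason = ""
    report = CriteriaReport(c1, c2, c3, c4, c5, c6, c7, reason=reason)
    return report, desc, r_sig


def extract_mature(window: CandidateWindow, hit: HomologyHit) -> tuple[str, tuple[int, int]]:
    """The window subsequence aligned to the query miRNA, in U-space."""
    ms, me = window.mature_span
    return window.seq[ms:me], (ms, me)


def select_best(passing: Sequence[Prediction]) -> Prediction | None:
    """Among passing windows of one hit: max MFEI, then max R, then the
    shortest window, then the smallest start (fully deterministic)."""
    if not passing:
        return None
    return max(
        passing,
        key=lambda p: (
            p.descriptors.mfei if p.descriptors.mfei is not None else float("-inf"),
            p.r_signature,
            -len(p.precursor),
            -p.precursor.window_start,
        ),
    )


def _suffix(i: int) -> str:
    # bijective base-26: 0 -> a, 25 -> z, 26 -> aa
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def name_predictions(
    predictions: Sequence[Prediction], species_prefix: str
) -> list[Prediction]:
    """Assign miRBase-style names; identical matures within a family are
    collapsed to one prediction with merged provenance.

    Distinct mature sequences in a family receive suffixes a, b, c ... in
    sorted-sequence order, so naming is independent of input order.
    """
    by_family: dict[str, dict[str, Prediction]] = {}
    for p in predictions:
        fam = by_family.setdefault(p.family, {})
        if p.mature_seq in fam:
            fam[p.mature_seq].provenance.append(p.precursor.id)
        else:
            fam[p.mature_seq] = p
            if not p.provenance:
                p.provenance = [p.precursor.id]
    named: list[Prediction] = []
    for family in sorted(by_family):
        matures = sorted(by_family[family])
        for i, mat in enumerate(matures):
            p = by_family[family][mat]
            p.name = f"{species_prefix}-miR{family[3:]}{_suffix(i)}"
            named.append(p)
    return named


@dataclass
class PipelineConfig:
    """Declarative inputs and knobs for a full prediction run."""

    queries: Sequence[SequenceRecord]
    subjects: Sequence[SequenceRecord]
    cutoffs: CutoffSet
    catalog: SignatureCatalog
    proteins: Sequence[SequenceRecord] = ()
    species_prefix: str = "pvu"
    word_size: int = 7
    max_mismatches: int = 3
    min_len: int = 55
    max_len: int = 505
    stride: int = 1
    r_min: float = 2.5
    backend: FoldingBackend | None = None


@dataclass
class StageReport:
    """Counts surviving each stage of the filter chain."""

    n_queries: int = 0
    n_subjects: int = 0
    n_hits: int = 0
    n_windows: int = 0
    n_after_coding: int = 0
    n_passing_windows: int = 0
    n_precursors: int = 0
    n_mature: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("queries", self.n_queries),
            ("subjects", self.n_subjects),
            ("homology_hits", self.n_hits),
            ("candidate_windows", self.n_windows),
            ("after_coding_filter", self.n_after_coding),
            ("windows_passing_criteria", self.n_passing_windows),
            ("predicted_precursors", self.n_precursors),
            ("predicted_mature", self.n_mature),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def query_family(query_id: str) -> str:
    """miRNA family of a query from its miRBase-style name."""
    return parse_mirna_name(query_id).family


def run_pipeline(config: PipelineConfig) -> tuple[list[Prediction], StageReport]:
    """Scan -> windows -> coding filter -> criteria -> selection -> naming.

    Output is deterministic and invariant to subject input order; every
    returned prediction passes all seven criteria.
    """
    if not config.queries:
        raise ValueError("no query miRNAs supplied")
    if config.cutoffs is None or config.catalog is None:
        raise ValueError("cutoffs and signature catalog are required")
    backend = config.backend or BuiltinBackend()
    report = StageReport(n_queries=len(config.queries), n_subjects=len(config.subjects))

    subjects = sorted(config.subjects, key=lambda s: s.id)
    subject_by_id = {s.id: s for s in subjects}
    hits = scan_homologs(
        config.queries, subjects, word_size=config.word_size,
        max_mismatches=config.max_mismatches,
    )
    hits.sort(key=lambda h: (h.subject_id, h.subject_start, h.subject_end, h.strand, h.query_id))
    report.n_hits = len(hits)

    windows_per_hit: list[tuple[HomologyHit, list[CandidateWindow]]] = []
    n_windows = 0
    for hit in hits:
        wins = enumerate_windows(
            subject_by_id[hit.subject_id], hit,
            min_len=config.min_len, max_len=config.max_len, stride=config.stride,
        )
        n_windows += len(wins)
        windows_per_hit.append((hit, wins))
    report.n_windows = n_windows

    if config.proteins:
        # scan each subject once; a window is coding iff it contains a
        # qualifying translated segment (equivalent to filtering windows
        # one by one, see homology.coding_segments)
        seg_cache: dict[str, list[tuple[int, int]]] = {}
        filtered: list[tuple[HomologyHit, list[CandidateWindow]]] = []
        n_after = 0
        for hit, wins in windows_per_hit:
            segs = seg_cache.get(hit.subject_id)
            if segs is None:
                segs = coding_segments(subject_by_id[hit.subject_id].seq, config.proteins)
                seg_cache[hit.subject_id] = segs
            kept = [
                w for w in wins
                if not any(w.window_start <= a and b <= w.window_end for a, b in segs)
            ]
            n_after += len(kept)
            filtered.append((hit, kept))
        windows_per_hit = filtered
        report.n_after_coding = n_after
    else:
        report.n_after_coding = n_windows

    selected: list[Prediction] = []
    n_passing = 0
    for hit, wins in windows_per_hit:
        family = query_family(hit.query_id)
        passing: list[Prediction] = []
        for w in wins:
            crit, desc, r_sig = apply_criteria(
                w, config.cutoffs, config.catalog, family,
                backend=backend, r_min=config.r_min,
            )
            if crit.overall:
                mature_seq, mspan = extract_mature(w, hit)
                passing.append(
                    Prediction(
                        precursor=w, mature_seq=mature_seq, mature_span=mspan,
                        family=family, descriptors=desc, r_signature=r_sig,
                        report=crit,
                    )
                )
        n_passing += len(passing)
        best = select_best(passing)
        if best is not None:
            selected.append(best)
    report.n_passing_windows = n_passing
    report.n_precursors = len(selected)

    named = name_predictions(selected, config.species_prefix)
    report.n_mature = len(named)
    return named, report


def predictions_gff3(predictions: Sequence[Prediction]) -> str:
    """GFF3 of precursor and mature coordinates on the subject sequences."""
    lines = ["##gff-version 3"]
    for p in predictions:
        w = p.precursor
        lines.append(
            "\t".join(
                [
                    w.subject_id, "mirsig", "miRNA_primary_transcript",
                    str(w.window_start + 1), str(w.window_end), ".",
                    w.strand, ".", f"ID={p.name}-precursor;Name={p.name}",
                ]
            )
        )
        h = w.hit
        lines.append(
            "\t".join(
                [
                    w.subject_id, "mirsig", "miRNA",
                    str(h.subject_start + 1), str(h.subject_end), ".",
                    w.strand, ".",
                    f"ID={p.name};Parent={p.name}-precursor;Name={p.name}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def predictions_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    """Tabulate predictions for TSV export (1-based coordinates)."""
    rows = []
    for p in predictions:
        w = p.precursor
        rows.append(
            {
                "name": p.name,
                "family": p.family,
                "mature_seq": p.mature_seq,
                "mature_len": len(p.mature_seq),
                "precursor_seq": w.seq,
                "subject": w.subject_id,
                "start": w.window_start + 1,
                "end": w.window_end,
                "strand": w.strand,
                "mfei": p.descriptors.mfei,
                "amfe": p.descriptors.amfe,
                "au_pct": p.descriptors.au_pct,
                "nq": p.descriptors.nq,
                "nd": p.descriptors.nd,
                "npb": p.descriptors.npb,
                "r_signature": p.r_signature,
                "provenance": ";".join(p.provenance),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "family", "mature_seq", "mature_len", "precursor_seq",
            "subject", "start", "end", "strand", "mfei", "amfe", "au_pct",
            "nq", "nd", "npb", "r_signature", "provenance",
        ],
    )
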