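"""Seeded generators for every input the pipeline consumes, with ground
truth, so all stages are testable without any external download.

The central generator plants an idealized pre-miRNA hairpin: a random
mature arm, a loop, the reverse-complement star arm with a configurable
number of planted stem mismatches, and random flanks carrying
non-overlapping copies of the family's SSR signature motif outside the
duplex. Each draw is folded with the built-in engine and redrawn until
the planted stem is the one realized in the MFE structure, so duplex
geometry, descriptor distributions and SSR densities are all known
exactly for every emitted hairpin.

Corpus-level generators assemble the full study design: known miRNA
families sharing a signature motif, EST-like subjects with planted
homologous precursors (both strands), decoy subjects (random, dinucleotide
-shuffled, and protein-coding), a reference hairpin population for cutoff
derivation, and a small-RNA read library supporting a subset of matures.
Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .seqio import CollapsedRead, SequenceRecord, revcomp, to_dna

__all__ = [
    "HairpinSpec",
    "PlantedTruth",
    "SyntheticCorpus",
    "make_precursor",
    "make_family",
    "embed_in_est",
    "make_decoys",
    "make_reference_set",
    "make_reads",
    "make_corpus",
    "dinucleotide_shuffle",
]

_RNA = np.array(list("ACGU"))
# partners that do NOT pair with a given base (no Watson-Crick, no wobble)
_NONPAIRING = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}


@dataclass(frozen=True)
class HairpinSpec:
    """Parameters of one planted pre-miRNA hairpin."""

    mature_len: int = 21
    stem_mismatches: int = 2
    loop_len: int = 8
    flank_len: int = 15
    gc_bias: float = 0.5
    signature_motif: str = "UUG"
    signature_copies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_mismatches >= 6:
            raise ValueError("stem_mismatches must be < 6 to satisfy the duplex criterion")
        total = self.mature_len * 2 + self.loop_len + 2 * self.flank_len
        if not (55 <= total <= 505):
            raise ValueError(f"total precursor length {total} outside [55, 505]")


@dataclass
class PlantedTruth:
    """Ground truth for one planted hairpin."""

    id: str
    mature_seq: str
    mature_span: tuple[int, int]
    family: str = ""
    motif: str = ""
    spec: HairpinSpec | None = None


@dataclass
class SyntheticCorpus:
    """A complete fixture bundle for an end-to-end pipeline run."""

    known_precursors: list[SequenceRecord]
    queries: list[SequenceRecord]
    subjects: list[SequenceRecord]
    proteins: list[SequenceRecord]
    reads: list[CollapsedRead]
    planted: dict[str, PlantedTruth]  # subject id -> truth (subject coords)
    planted_strand: dict[str, str]
    decoy_ids: set[str]
    families: dict[str, list[SequenceRecord]]


def _random_seq(rng: np.random.Generator, n: int, gc_bias: float = 0.5,
                alphabet: str = "ACGU") -> str:
    if alphabet == "ACGU":
        p = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
        return "".join(rng.choice(_RNA, size=n, p=p))
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=n))


def _plant_motif(flank: list[str], rng: np.random.Generator, motif: str,
                 n_copies: int) -> None:
    """Overwrite non-overlapping slots of the flank with motif copies."""
    k = len(motif)
    slots = len(flank) // k
    if n_copies > slots:
        raise ValueError(
            f"cannot place {n_copies} copies of a {k}-mer in a {len(flank)}-nt flank"
        )
    chosen = rng.choice(slots, size=n_copies, replace=False)
    for s in sorted(chosen):
        flank[s * k : (s + 1) * k] = list(motif)


def make_precursor(
    spec: HairpinSpec,
    mature: str | None = None,
    name: str = "syn-precursor",
    verify: bool = True,
    max_tries: int = 60,
) -> tuple[SequenceRecord, tuple[int, int], PlantedTruth]:
    """Generate one planted hairpin precursor.

    Layout: 5' flank + mature + loop + star + 3' flank, where star is the
    reverse complement of the mature with ``stem_mismatches`` substitutions
    planted in its interior, flanks and loop are random at the same GC
    bias, and ``signature_copies`` non-overlapping motif copies are written
    into the flanks (outside the duplex). Deterministic under the spec's
    seed.

    The pair-maximizing built-in energy model will happily recruit free
    bases into alternative stems, so with ``verify=True`` (the default)
    the construct is folded and redrawn until the planted geometry is
    realized in the MFE structure: duplex mismatches equal to
    ``stem_mismatches``, mature on one arm outside the terminal loop, star
    unbroken. A few redraws usually suffice; if ``max_tries`` is exhausted
    (possible for a fixed mature with strong self-structure) the last
    attempt is returned with a warning.
    """
    import warnings

    rng = np.random.default_rng(spec.seed)
    if mature is not None and len(mature) != spec.mature_len:
        spec = replace(spec, mature_len=len(mature))

    def build() -> tuple[str, tuple[int, int], str]:
        mat = mature if mature is not None else _random_seq(
            rng, spec.mature_len, gc_bias=spec.gc_bias
        )
        star = list(revcomp(mat))
        if spec.stem_mismatches > 0:
            interior = np.arange(2, len(star) - 2)
            picks = rng.choice(interior, size=spec.stem_mismatches, replace=False)
            for pos in picks:
                # substitute so the position no longer pairs its mature partner
                options = _NONPAIRING[mat[len(mat) - 1 - pos]]
                star[pos] = options[rng.integers(len(options))]
        loop = _random_seq(rng, spec.loop_len, gc_bias=spec.gc_bias)
        flank5 = list(_random_seq(rng, spec.flank_len, gc_bias=spec.gc_bias))
        flank3 = list(_random_seq(rng, spec.flank_len, gc_bias=spec.gc_bias))
        n5 = (spec.signature_copies + 1) // 2
        _plant_motif(flank5, rng, spec.signature_motif, n5)
        _plant_motif(flank3, rng, spec.signature_motif, spec.signature_copies - n5)
        seq = "".join(flank5) + mat + loop + "".join(star) + "".join(flank3)
        return seq, (len(flank5), len(flank5) + len(mat)), mat

    if verify:
        from .folding import analyze_duplex, fold_profile

        seq, span, mat = "", (0, 0), ""
        for _ in range(max_tries):
            seq, span, mat = build()
            dup = analyze_duplex(fold_profile(seq), span)
            if (
                dup.mismatches == spec.stem_mismatches
                and dup.same_arm
                and dup.star_contiguous
                and not dup.overlaps_loop
            ):
                break
        else:
            warnings.warn(
                f"{name}: planted geometry not realized after {max_tries} draws; "
                "returning last attempt"
            )
    else:
        seq, span, mat = build()

    rec = SequenceRecord(id=name, seq=seq)
    truth = PlantedTruth(
        id=name, mature_seq=mat, mature_span=span,
        motif=spec.signature_motif, spec=spec,
    )
    return rec, span, truth


def make_family(
    n_members: int,
    shared_motif: str,
    seed: int,
    family_number: int = 9001,
    species_prefix: str = "syn",
    spec: HairpinSpec | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """A miRNA family: (precursor records, mature records).

    All members carry ``shared_motif`` at per-member density R >= 2.5 by
    construction; matures are otherwise randomized. Names follow miRBase
    conventions (``syn-MIR9001a`` / ``syn-miR9001a``).
    """
    if n_members < 1:
        raise ValueError("family needs at least one member")
    base = spec or HairpinSpec()
    precursors: list[SequenceRecord] = []
    matures: list[SequenceRecord] = []
    for i in range(n_members):
        letter = chr(ord("a") + i) if i < 26 else f"a{chr(ord('a') + i - 26)}"
        member_spec = replace(
            base, signature_motif=shared_motif, seed=seed * 1000 + i
        )
        pre, span, truth = make_precursor(
            member_spec, name=f"{species_prefix}-MIR{family_number}{letter}"
        )
        precursors.append(pre)
        matures.append(
            SequenceRecord(
                id=f"{species_prefix}-miR{family_number}{letter}",
                seq=truth.mature_seq,
            )
        )
    return precursors, matures


def embed_in_est(
    precursor: SequenceRecord,
    flank_len: int,
    seed: int,
    strand: str = "+",
    mature_span: tuple[int, int] | None = None,
    subject_id: str | None = None,
) -> tuple[SequenceRecord, PlantedTruth]:
    """Embed a precursor in random EST-like DNA flanks.

    The returned truth carries precursor and mature spans in subject
    (+ strand) coordinates; with ``strand='-'`` the whole subject is
    reverse-complemented so the planted mature lies on the minus strand.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    rng = np.random.default_rng(seed)
    up = _random_seq(rng, flank_len, alphabet="ACGT")
    down = _random_seq(rng, flank_len, alphabet="ACGT")
    body = to_dna(precursor.seq)
    subject_seq = up + body + down
    pre_span = (flank_len, flank_len + len(body))
    if mature_span is not None:
        mat_span = (flank_len + mature_span[0], flank_len + mature_span[1])
    else:
        mat_span = pre_span
    if strand == "-":
        n = len(subject_seq)
        subject_seq = to_dna(revcomp(subject_seq))
        pre_span = (n - pre_span[1], n - pre_span[0])
        mat_span = (n - mat_span[1], n - mat_span[0])
    sid = subject_id or f"{precursor.id}|est"
    rec = SequenceRecord(id=sid, seq=subject_seq)
    truth = PlantedTruth(
        id=sid,
        mature_seq=precursor.seq[mature_span[0]:mature_span[1]] if mature_span else precursor.seq,
        mature_span=mat_span,
    )
    return rec, truth


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Random Eulerian-path shuffle of the dinucleotide transition multigraph;
    first and last letters are preserved, as the method requires.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    for _ in range(10_000):
        # choose a random terminal edge for every non-final vertex
        lasts: dict[str, str] = {}
        ok = True
        for a in letters:
            if a == last:
                continue
            if not edges[a]:
                continue
            lasts[a] = edges[a][rng.integers(len(edges[a]))]
        # the chosen terminal edges must form a tree rooted at `last`
        for a in lasts:
            node, steps = a, 0
            while node != last and steps <= len(letters):
                if node not in lasts:
                    ok = False
                    break
                node = lasts[node]
                steps += 1
            if not ok or (node != last and steps > len(letters)):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled_edges: dict[str, list[str]] = {}
    for a in letters:
        pool = list(edges[a])
        if a in lasts:
            pool.remove(lasts[a])
        perm = rng.permutation(len(pool))
        ordered = [pool[i] for i in perm]
        if a in lasts:
            ordered.append(lasts[a])
        shuffled_edges[a] = ordered
    out = [seq[0]]
    cursors = {a: 0 for a in letters}
    node = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[node][cursors[node]]
        cursors[node] += 1
        out.append(nxt)
        node = nxt
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    codons = []
    for aa in protein:
        options = sorted(by_aa[aa])
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def make_proteins(n: int, length: int, seed: int) -> list[SequenceRecord]:
    """Random protein fixtures for the coding-exclusion path."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(id=f"syn-prot{i}", seq="".join(rng.choice(_AA, size=length)))
        for i in range(n)
    ]


def make_decoys(
    n: int,
    length_dist: tuple[int, int] | Callable[[np.random.Generator], int],
    kind: str,
    seed: int,
    sources: Sequence[SequenceRecord] = (),
    proteins: Sequence[SequenceRecord] = (),
) -> list[SequenceRecord]:
    """Negative subject sequences.

    ``kind``: 'random' (iid DNA), 'shuffled' (dinucleotide shuffles of the
    supplied source sequences), or 'coding' (random DNA embedding a
    reverse-translated 30-aa stretch of a supplied protein, guaranteed to
    trip the coding filter).
    """
    rng = np.random.default_rng(seed)

    def draw_len() -> int:
        if callable(length_dist):
            return int(length_dist(rng))
        return int(rng.integers(length_dist[0], length_dist[1] + 1))

    out: list[SequenceRecord] = []
    for i in range(n):
        if kind == "random":
            seq = _random_seq(rng, draw_len(), alphabet="ACGT")
        elif kind == "shuffled":
            if not sources:
                raise ValueError("shuffled decoys need source sequences")
            src = sources[i % len(sources)]
            seq = dinucleotide_shuffle(to_dna(src.seq), rng)
        elif kind == "coding":
            if not proteins:
                raise ValueError("coding decoys need protein fixtures")
            prot = proteins[i % len(proteins)]
            start = int(rng.integers(0, max(1, len(prot.seq) - 30)))
            orf = _reverse_translate(prot.seq[start : start + 30], rng)
            length = max(draw_len(), len(orf) + 20)
            pad5 = _random_seq(rng, (length - len(orf)) // 2, alphabet="ACGT")
            pad3 = _random_seq(rng, length - len(orf) - len(pad5), alphabet="ACGT")
            seq = pad5 + orf + pad3
        else:
            raise ValueError(f"unknown decoy kind {kind!r}")
        out.append(SequenceRecord(id=f"decoy-{kind}-{i}", seq=seq))
    return out


def make_reference_set(
    n: int = 1000,
    seed: int = 0,
    motifs: Sequence[str] = ("UUG", "AUU", "AAU", "UUU", "CUC"),
) -> list[SequenceRecord]:
    """A reference hairpin population for deriving descriptor cutoffs.

    Hairpin geometry is randomized around realistic plant precursor values
    (mature 19-24 nt, loop 6-12, flanks 10-25, GC bias 0.35-0.65) so the
    descriptor distributions have non-degenerate spread.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = HairpinSpec(
            mature_len=int(rng.integers(19, 25)),
            stem_mismatches=int(rng.integers(0, 4)),
            loop_len=int(rng.integers(6, 13)),
            flank_len=int(rng.integers(10, 26)),
            gc_bias=float(rng.uniform(0.35, 0.65)),
            signature_motif=str(motifs[int(rng.integers(len(motifs)))]),
            signature_copies=int(rng.integers(2, 4)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, _, _ = make_precursor(spec, name=f"syn-ref{i}")
        out.append(rec)
    return out


def make_reads(
    matures: Sequence[SequenceRecord],
    seed: int,
    support_fraction: float = 0.7,
    noise_reads: int = 50,
) -> list[CollapsedRead]:
    """A collapsed small-RNA library supporting a subset of matures.

    Supported matures get a log-normally distributed count; noise reads
    are random 14-24 nt sequences, plus a handful of sub-14-nt fragments
    that a correct length filter must drop.
    """
    rng = np.random.default_rng(seed)
    reads: list[CollapsedRead] = []
    for m in matures:
        if rng.uniform() < support_fraction:
            count = max(1, int(rng.lognormal(mean=3.0, sigma=1.5)))
            reads.append(CollapsedRead(seq=m.seq, count=count))
    for _ in range(noise_reads):
        n = int(rng.integers(14, 25))
        reads.append(CollapsedRead(seq=_random_seq(rng, n), count=int(rng.integers(1, 20))))
    # short degradation fragments a correct length filter must drop
    for _ in range(5):
        n = int(rng.integers(8, 14))
        reads.append(CollapsedRead(seq=_random_seq(rng, n), count=int(rng.integers(1, 5))))
    return reads


def make_corpus(
    n_families: int = 25,
    members_range: tuple[int, int] = (1, 4),
    n_planted: int = 20,
    n_decoys: int = 200,
    est_flank: tuple[int, int] = (60, 140),
    minus_fraction: float = 0.3,
    seed: int = 0,
) -> SyntheticCorpus:
    """Assemble the full synthetic study: known families, planted ESTs,
    decoys, proteins and a read library, with ground truth."""
    rng = np.random.default_rng(seed)
    all_motifs = [a + b + c for a in "ACGU" for b in "ACGU" for c in "ACGU"]
    motif_idx = rng.choice(len(all_motifs), size=n_families, replace=False)

    families: dict[str, list[SequenceRecord]] = {}
    known_precursors: list[SequenceRecord] = []
    queries: list[SequenceRecord] = []
    fam_info: list[tuple[str, str, list[SequenceRecord]]] = []
    for f in range(n_families):
        fam_num = 9001 + f
        motif = all_motifs[int(motif_idx[f])]
        n_members = int(rng.integers(members_range[0], members_range[1] + 1))
        pres, mats = make_family(
            n_members, motif, seed=int(rng.integers(0, 2**31 - 1)),
            family_number=fam_num,
        )
        fam_id = f"MIR{fam_num}"
        families[fam_id] = pres
        known_precursors.extend(pres)
        queries.extend(mats)
        fam_info.append((fam_id, motif, mats))

    proteins = make_proteins(5, 120, seed=int(rng.integers(0, 2**31 - 1)))

    # The family signature actually carried by a true homolog is whatever
    # motif wins the family vote, which chance repeats can decide; plant
    # that derived signature so planted homologs behave like real family
    # members under criterion 7.
    from .ssr import family_signature

    derived_motif: dict[str, str] = {}
    for fam_id, motif, _mats in fam_info:
        sig = family_signature(families[fam_id], family=fam_id)
        derived_motif[fam_id] = sig.motif if sig is not None else motif

    subjects: list[SequenceRecord] = []
    planted: dict[str, PlantedTruth] = {}
    planted_strand: dict[str, str] = {}
    for i in range(n_planted):
        fam_id, motif, mats = fam_info[int(rng.integers(len(fam_info)))]
        motif = derived_motif[fam_id]
        mat = mats[int(rng.integers(len(mats)))]
        spec = HairpinSpec(
            mature_len=len(mat.seq),
            signature_motif=motif,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pre, mspan, _ = make_precursor(spec, mature=mat.seq, name=f"planted-{i}")
        strand = "-" if rng.uniform() < minus_fraction else "+"
        flank = int(rng.integers(est_flank[0], est_flank[1] + 1))
        subj, truth = embed_in_est(
            pre, flank, seed=int(rng.integers(0, 2**31 - 1)), strand=strand,
            mature_span=mspan, subject_id=f"est-planted-{i}",
        )
        truth.family = fam_id
        truth.motif = motif
        truth.mature_seq = mat.seq
        subjects.append(subj)
        planted[subj.id] = truth
        planted_strand[subj.id] = strand

    n_rand = int(round(n_decoys * 0.6))
    n_shuf = int(round(n_decoys * 0.2))
    n_code = n_decoys - n_rand - n_shuf
    decoys = (
        make_decoys(n_rand, (150, 400), "random", seed=int(rng.integers(0, 2**31 - 1)))
        + make_decoys(
            n_shuf, (150, 400), "shuffled", seed=int(rng.integers(0, 2**31 - 1)),
            sources=subjects or known_precursors,
        )
        + make_decoys(
            n_code, (150, 400), "coding", seed=int(rng.integers(0, 2**31 - 1)),
            proteins=proteins,
        )
    )
    subjects = subjects + decoys
    decoy_ids = {d.id for d in decoys}

    reads = make_reads(queries, seed=int(rng.integers(0, 2**31 - 1)))

    return SyntheticCorpus(
        known_precursors=known_precursors,
        queries=queries,
        subjects=subjects,
        proteins=proteins,
        reads=reads,
        planted=planted,
        planted_strand=planted_strand,
        decoy_ids=decoy_ids,
        families=families,
    )
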