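"""Homology scanning (seed-and-extend vs brute force), window enumeration
counts, and the translated coding exclusion."""

import random

import pytest

from mirsig.homology import (
    CandidateWindow,
    HomologyHit,
    coding_filter,
    coding_segments,
    enumerate_windows,
    scan_homologs,
)
from mirsig.seqio import SequenceRecord, revcomp, to_rna


def brute_force_hits(queries, subjects, word_size=7, max_mismatches=3):
    """All-offsets Hamming scan with the exact-seed condition."""
    out = set()
    for q in queries:
        qseq = to_rna(q.seq)
        if len(qseq) < word_size:
            continue
        for subj in subjects:
            n = len(subj.seq)
            for strand in "+-":
                s = to_rna(subj.seq) if strand == "+" else revcomp(subj.seq)
                for start in range(0, n - len(qseq) + 1):
                    window = s[start : start + len(qseq)]
                    mm = sum(1 for a, b in zip(qseq, window) if a != b)
                    has_seed = any(
                        qseq[o : o + word_size] == window[o : o + word_size]
                        for o in range(len(qseq) - word_size + 1)
                    )
                    if mm <= max_mismatches and has_seed:
                        if strand == "+":
                            span = (start, start + len(qseq))
                        else:
                            span = (n - start - len(qseq), n - start)
                        out.add((q.id, subj.id, span, strand, mm))
    return out


def embed(subject, query, pos):
    return subject[:pos] + query + subject[pos + len(query) :]


RNG = random.Random(21)
BACKGROUND = "".join(RNG.choice("ACGT") for _ in range(300))
QUERY = "".join(RNG.choice("ACGU") for _ in range(21))


class TestScanHomologs:
    def test_exact_copy_found(self):
        subj = SequenceRecord(id="s", seq=embed(BACKGROUND, QUERY.replace("U", "T"), 140))
        hits = scan_homologs([SequenceRecord(id="q", seq=QUERY)], [subj])
        plus = [h for h in hits if h.strand == "+" and h.mismatches == 0]
        assert len(plus) == 1
        assert plus[0].subject_span == (140, 161)

    def test_three_mismatches_with_intact_seed_retained(self):
        mutated = QUERY[:-3] + "".join(
            {"A": "C", "C": "A", "G": "U", "U": "G"}[c] for c in QUERY[-3:]
        )
        subj = SequenceRecord(id="s", seq=embed(BACKGROUND, mutated.replace("U", "T"), 140))
        hits = scan_homologs([SequenceRecord(id="q", seq=QUERY)], [subj])
        assert any(h.mismatches == 3 and h.subject_span == (140, 161) for h in hits)

    def test_four_mismatches_rejected(self):
        mutated = QUERY[:-4] + "".join(
            {"A": "C", "C": "A", "G": "U", "U": "G"}[c] for c in QUERY[-4:]
        )
        subj = SequenceRecord(id="s", seq=embed(BACKGROUND, mutated.replace("U", "T"), 140))
        hits = scan_homologs([SequenceRecord(id="q", seq=QUERY)], [subj])
        assert not any(h.subject_span == (140, 161) for h in hits)

    def test_minus_strand_found(self):
        subj = SequenceRecord(
            id="s", seq=embed(BACKGROUND, revcomp(QUERY).replace("U", "T"), 100)
        )
        hits = scan_homologs([SequenceRecord(id="q", seq=QUERY)], [subj])
        minus = [h for h in hits if h.strand == "-" and h.mismatches == 0]
        assert len(minus) == 1
        assert minus[0].subject_span == (100, 121)

    def test_short_query_skipped_with_warning(self):
        subj = SequenceRecord(id="s", seq="ACGTACGTACGT")
        with pytest.warns(UserWarning, match="shorter than word size"):
            hits = scan_homologs([SequenceRecord(id="q", seq="ACGU")], [subj])
        assert hits == []

    def test_matches_brute_force_scan(self):
        rng = random.Random(33)
        queries = [
            SequenceRecord(id=f"q{i}", seq="".join(rng.choice("ACGU") for _ in range(20)))
            for i in range(3)
        ]
        subjects = []
        for i in range(4):
            base = "".join(rng.choice("ACGT") for _ in range(250))
            q = rng.choice(queries).seq.replace("U", "T")
            # plant exact and mutated copies
            base = embed(base, q, 30)
            mutated = list(q)
            for p in rng.sample(range(20), 2):
                mutated[p] = rng.choice("ACGT")
            base = embed(base, "".join(mutated), 120)
            subjects.append(SequenceRecord(id=f"s{i}", seq=base))
        got = {
            (h.query_id, h.subject_id, h.subject_span, h.strand, h.mismatches)
            for h in scan_homologs(queries, subjects)
        }
        assert got == brute_force_hits(queries, subjects)


class TestEnumerateWindows:
    def hit(self, start, end, strand="+"):
        return HomologyHit(
            query_id="q", subject_id="s", subject_start=start,
            subject_end=end, strand=strand, mismatches=0,
        )

    def test_single_length_placement_count(self):
        subj = SequenceRecord(id="s", seq="A" * 600)
        wins = enumerate_windows(subj, self.hit(300, 321), min_len=55, max_len=55)
        assert len(wins) == 35  # 55 - 21 + 1

    def test_bounded_subject(self):
        subj = SequenceRecord(id="s", seq="A" * 60)
        wins = enumerate_windows(subj, self.hit(20, 41), min_len=55, max_len=505)
        by_len = {}
        for w in wins:
            by_len.setdefault(len(w), 0)
            by_len[len(w)] += 1
        assert set(by_len) == {55, 56, 57, 58, 59, 60}
        assert by_len[55] == 6

    def test_hit_longer_than_max_len(self):
        subj = SequenceRecord(id="s", seq="A" * 600)
        wins = enumerate_windows(subj, self.hit(10, 100), min_len=55, max_len=80)
        assert wins == []

    def test_subject_shorter_than_min_len(self):
        subj = SequenceRecord(id="s", seq="A" * 40)
        assert enumerate_windows(subj, self.hit(5, 26)) == []

    def test_count_matches_closed_form(self):
        rng = random.Random(8)
        for _ in range(25):
            n = rng.randint(80, 400)
            h0 = rng.randint(0, n - 25)
            h1 = h0 + rng.randint(15, 24)
            lo, hi = 55, rng.randint(60, 200)
            subj = SequenceRecord(id="s", seq="A" * n)
            wins = enumerate_windows(subj, self.hit(h0, h1), min_len=lo, max_len=hi)
            expected = sum(
                max(0, min(h0, n - length) - max(0, h1 - length) + 1)
                for length in range(lo, hi + 1)
                if length <= n and length >= h1 - h0
            )
            assert len(wins) == expected
            assert all(w.window_start <= h0 and h1 <= w.window_end for w in wins)

    def test_minus_strand_orientation(self):
        body = "".join(random.Random(4).choice("ACGT") for _ in range(120))
        subj = SequenceRecord(id="s", seq=body)
        h = self.hit(40, 61, strand="-")
        wins = enumerate_windows(subj, h, min_len=60, max_len=60)
        for w in wins:
            ms, me = w.mature_span
            assert w.seq[ms:me] == revcomp(body[40:61])


def window_of(seq, name="c"):
    hit = HomologyHit(
        query_id="q", subject_id=name, subject_start=0,
        subject_end=min(21, len(seq)), strand="+", mismatches=0,
    )
    return CandidateWindow(
        subject_id=name, window_start=0, window_end=len(seq), strand="+",
        seq=to_rna(seq), hit=hit, mature_span=(0, min(21, len(seq))),
    )


class TestCodingFilter:
    PROTEIN = SequenceRecord(
        id="p", seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA"
    )

    def coding_dna(self):
        from Bio.Seq import Seq

        codons = {
            "M": "ATG", "K": "AAA", "T": "ACC", "A": "GCC", "Y": "TAT",
            "I": "ATT", "Q": "CAA", "R": "CGT", "S": "TCT", "F": "TTT",
            "V": "GTT", "H": "CAT", "L": "CTG", "E": "GAA", "G": "GGT",
        }
        dna = "".join(codons[aa] for aa in self.PROTEIN.seq[:30])
        assert str(Seq(dna).translate()) == self.PROTEIN.seq[:30]
        return dna

    def test_exact_translated_copy_rejected(self):
        cand = window_of("ACGTAC" + self.coding_dna() + "GGTACG")
        kept, rejected = coding_filter([cand], [self.PROTEIN])
        assert kept == [] and rejected == [cand]

    def test_unrelated_sequence_kept(self):
        cand = window_of("ACGT" * 30)
        kept, rejected = coding_filter([cand], [self.PROTEIN])
        assert rejected == [] and kept == [cand]

    def test_identity_below_threshold_kept(self):
        # corrupt every 4th codon: 75% identity in every 20-aa window
        dna = self.coding_dna()
        codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
        for i in range(0, len(codons), 4):
            codons[i] = "TGG"  # tryptophan, absent from the protein prefix
        cand = window_of("ACGTAC" + "".join(codons) + "GGTACG")
        kept, rejected = coding_filter([cand], [self.PROTEIN])
        assert rejected == [] and kept == [cand]

    def test_precomputed_rejection_list(self):
        cands = [window_of("ACGT" * 20, name=f"s{i}") for i in range(3)]
        kept, rejected = coding_filter(
            cands, [], rejected_ids=[cands[1].id]
        )
        assert rejected == [cands[1]] and len(kept) == 2

    def test_segment_scan_agrees_with_per_candidate_filter(self):
        subject = "ACGTACGTAC" + self.coding_dna() + "TTGGCCAACGGT" * 8
        segs = coding_segments(subject, [self.PROTEIN])
        assert segs  # the planted ORF is detected
        for a, b in segs:
            # each reported 60-nt segment lies essentially on the planted ORF
            # (an 80%-identity window may overhang it by a few codons)
            overlap = min(b, 10 + 90) - max(a, 10)
            assert overlap >= 0.8 * (b - a)
        clean = coding_segments("ACGT" * 60, [self.PROTEIN])
        assert clean == []
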