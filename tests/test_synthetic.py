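"""Synthetic generators: reproducibility, planted structure and SSR
density guarantees, EST embedding coordinates, and decoy construction."""

import io
from collections import Counter

import numpy as np
import pytest

from mirsig import synthetic
from mirsig.folding import analyze_duplex
from mirsig.homology import coding_segments, scan_homologs
from mirsig.seqio import SequenceRecord, read_collapsed_reads, revcomp, to_rna
from mirsig.ssr import build_catalog, family_signature, r_value
from mirsig.synthetic import HairpinSpec, dinucleotide_shuffle, make_precursor


class TestMakePrecursor:
    def test_planted_duplex_geometry(self, backend):
        spec = HairpinSpec(seed=7)
        rec, mspan, truth = make_precursor(spec)
        dup = analyze_duplex(backend.fold(rec.seq), mspan)
        assert dup.mismatches == spec.stem_mismatches
        assert dup.same_arm and dup.star_contiguous and not dup.overlaps_loop

    def test_signature_density_bound(self):
        spec = HairpinSpec(seed=3, signature_copies=3)
        rec, _, truth = make_precursor(spec)
        assert r_value(rec.seq, spec.signature_motif) >= 3.0

    def test_deterministic_under_seed(self):
        a = make_precursor(HairpinSpec(seed=11))[0]
        b = make_precursor(HairpinSpec(seed=11))[0]
        c = make_precursor(HairpinSpec(seed=12))[0]
        assert a.seq == b.seq
        assert a.seq != c.seq

    def test_fixed_mature_is_embedded_verbatim(self):
        mature = "UGUCUACCUGAGACUGUCCAG"
        rec, span, truth = make_precursor(HairpinSpec(seed=5), mature=mature)
        assert rec.seq[span[0] : span[1]] == mature

    def test_infeasible_motif_packing_rejected(self):
        spec = HairpinSpec(seed=1, flank_len=16, signature_copies=11)
        with pytest.raises(ValueError):
            make_precursor(spec)

    def test_length_invariant_enforced(self):
        with pytest.raises(ValueError):
            HairpinSpec(flank_len=0, loop_len=3, mature_len=10)  # total 26 < 55

    def test_excessive_mismatches_rejected(self):
        with pytest.raises(ValueError):
            HairpinSpec(stem_mismatches=6)


class TestMakeFamily:
    def test_signature_recovered(self):
        pres, mats = synthetic.make_family(4, "UUG", seed=11)
        sig = family_signature(pres, family="F")
        assert sig.motif == "UUG"
        assert len(mats) == 4

    def test_single_member_path(self):
        pres, mats = synthetic.make_family(1, "AAU", seed=2)
        assert len(pres) == 1
        assert r_value(pres[0].seq, "AAU") >= 2.5

    def test_disjoint_families_distinguished(self):
        p1, _ = synthetic.make_family(3, "UUG", seed=21, family_number=9201)
        p2, _ = synthetic.make_family(3, "GCA", seed=22, family_number=9202)
        cat = build_catalog({"MIR9201": p1, "MIR9202": p2})
        assert cat.get("MIR9201").motif == "UUG"
        assert cat.get("MIR9202").motif == "GCA"


class TestEmbedInEST:
    def test_truth_coordinates_plus_strand(self):
        rec, mspan, _ = make_precursor(HairpinSpec(seed=4))
        subj, truth = synthetic.embed_in_est(rec, 150, seed=8, mature_span=mspan)
        mat = to_rna(subj.seq[truth.mature_span[0] : truth.mature_span[1]])
        assert mat == rec.seq[mspan[0] : mspan[1]]

    def test_minus_strand_coordinates(self):
        rec, mspan, _ = make_precursor(HairpinSpec(seed=4))
        subj, truth = synthetic.embed_in_est(
            rec, 150, seed=8, strand="-", mature_span=mspan
        )
        mat = to_rna(subj.seq[truth.mature_span[0] : truth.mature_span[1]])
        assert revcomp(mat) == rec.seq[mspan[0] : mspan[1]]

    def test_scan_recovers_planted_span(self):
        rec, mspan, truth0 = make_precursor(HairpinSpec(seed=6))
        subj, truth = synthetic.embed_in_est(rec, 200, seed=9, mature_span=mspan)
        query = SequenceRecord(id="q", seq=truth0.mature_seq)
        hits = scan_homologs([query], [subj])
        assert any(
            h.subject_span == truth.mature_span and h.mismatches == 0 and h.strand == "+"
            for h in hits
        )

    def test_zero_flank_boundary(self):
        rec, mspan, _ = make_precursor(HairpinSpec(seed=4))
        subj, truth = synthetic.embed_in_est(rec, 0, seed=1, mature_span=mspan)
        assert len(subj.seq) == len(rec.seq)
        assert truth.mature_span == mspan


class TestDecoys:
    def test_coding_decoys_trip_the_coding_filter(self):
        proteins = synthetic.make_proteins(3, 120, seed=5)
        decoys = synthetic.make_decoys(
            15, (150, 250), "coding", seed=6, proteins=proteins
        )
        for d in decoys:
            assert coding_segments(d.seq, proteins), d.id

    def test_random_decoys_mostly_clean(self):
        proteins = synthetic.make_proteins(3, 120, seed=5)
        decoys = synthetic.make_decoys(15, (150, 250), "random", seed=7)
        dirty = sum(1 for d in decoys if coding_segments(d.seq, proteins))
        assert dirty <= 1

    def test_shuffled_decoys_preserve_dinucleotide_counts(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 300))
        shuf = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            return Counter(s[i : i + 2] for i in range(len(s) - 1))
        assert dinucs(shuf) == dinucs(seq)
        assert shuf != seq

    def test_zero_decoys(self):
        assert synthetic.make_decoys(0, (100, 200), "random", seed=1) == []


class TestCorpusAndReads:
    def test_corpus_bit_reproducible(self):
        a = synthetic.make_corpus(n_families=3, n_planted=2, n_decoys=6, seed=5)
        b = synthetic.make_corpus(n_families=3, n_planted=2, n_decoys=6, seed=5)
        assert [s.seq for s in a.subjects] == [s.seq for s in b.subjects]
        assert [q.seq for q in a.queries] == [q.seq for q in b.queries]

    def test_planted_truth_spans_hold(self, small_corpus):
        subj_by_id = {s.id: s for s in small_corpus.subjects}
        for sid, truth in small_corpus.planted.items():
            seq = to_rna(subj_by_id[sid].seq)
            segment = seq[truth.mature_span[0] : truth.mature_span[1]]
            if small_corpus.planted_strand[sid] == "+":
                assert segment == truth.mature_seq
            else:
                assert revcomp(segment) == truth.mature_seq

    def test_read_library_roundtrip_drops_short_fragments(self, small_corpus):
        buf = io.StringIO()
        for i, r in enumerate(small_corpus.reads):
            buf.write(f">read{i}_x{r.count}\n{r.seq}\n")
        back = read_collapsed_reads(io.StringIO(buf.getvalue()), min_len=14)
        assert all(len(r.seq) >= 14 for r in back)
        assert any(len(r.seq) < 14 for r in small_corpus.reads)
        kept_total = sum(r.count for r in small_corpus.reads if len(r.seq) >= 14)
        assert sum(r.count for r in back) == kept_total
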