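# mirsig

Homology + SSR-signature prediction of plant pre-miRNAs and mature
miRNAs.

Most plant miRNA families are conserved across species, so new miRNAs
can be found by scanning EST/GSS or genomic sequences for near-exact
copies of known mature miRNAs and asking whether the surrounding
sequence folds into a genuine pre-miRNA hairpin. `mirsig` implements
such a pipeline for researchers annotating miRNAs in plant species with
little existing small-RNA data. Two ideas distinguish it from
fixed-threshold pipelines:

1. **Descriptor cutoffs as 99%-probability regions.** Instead of fixed
   values, the acceptance ranges for precursor length, AU content, MFEI
   (minimal folding free energy index), normalized Shannon entropy NQ,
   normalized base-pair distance ND and base-pairing propensity Npb are
   the empirical region covering 99% of a reference precursor
   population.
2. **Family SSR signatures.** Each miRNA family carries a conserved
   trinucleotide simple-sequence-repeat motif — the k-mer present in all
   members with maximal average density R = count/L × 100. Requiring the
   candidate to carry its family's signature at R ≥ 2.5 removes most
   false positives surviving the folding filters.

A candidate window around a homology hit is accepted when seven criteria
hold: (1) hairpin with MFE < 0 and MFEI above the cutoff; (2) mature on
one arm, outside the terminal loop; (3) fewer than 6 mature/miRNA*
mismatches; (4) unbroken miRNA*; (5) AU% in range; (6) NQ, ND, Npb in
range; (7) family SSR signature present at R ≥ 2.5. The best window per
hit maximizes MFEI, then R.

The package ships a self-contained, exactly solvable folding engine
(per-pair energies, exhaustive-enumeration-validated MFE and McCaskill
pair probabilities), a pluggable backend interface for thermodynamic
folders, a seeded synthetic-data module that generates every input with
ground truth, and validation statistics (sensitivity/specificity/
PPV/NPV, read support, TPM, 2^−ΔCT). See `docs/methods.md` for the
science and the design choices.

## Worked example

Generate a synthetic study (8 known families, 5 planted precursors
hidden in EST-like subjects among 30 decoys), then predict:

```bash
mirsig simulate --out fixtures --seed 11 --families 8 --planted 5 --decoys 30
# wrote 35 subjects (5 planted, 30 decoys), 19 queries, 19 known precursors to fixtures

mirsig predict --queries fixtures/queries.fasta \
               --subjects fixtures/subjects.fasta \
               --precursors fixtures/known_precursors.fasta \
               --proteins fixtures/proteins.fasta \
               --out run --prefix syn --min-len 55 --max-len 115 --stride 3
# 10 hits -> 4620 windows -> 7 precursors -> 5 mature miRNAs
```

`run/stage_report.tsv` logs the counts surviving each filter stage:

```
stage                     count
queries                   19
subjects                  35
homology_hits             10
candidate_windows         4620
after_coding_filter       4620
windows_passing_criteria  718
predicted_precursors      7
predicted_mature          5
```

Ten homology hits (each planted hairpin is found twice — the mature arm
on one strand and the miRNA* arm on the other) spawn 4620 candidate
windows; 718 windows pass all seven criteria, the best window per hit
gives 7 precursors, and mature-level deduplication leaves 5 named
predictions. `run/predictions.tsv` holds one row per mature with its
descriptors:

```
name          family   mature_seq             mfei   r_signature
syn-miR9002a  MIR9002  ACGAAUCUAGGUGCUAUACGG  1.86   4.11
syn-miR9002b  MIR9002  ACGCAUCUAGUUGCUAUACGG  2.22   4.12
syn-miR9005a  MIR9005  GAUUGCCUCUUCUGGUCGUGU  1.94   4.00
...
```

MFEI ≈ 1.9–2.2 is the scale of the built-in energy model (cutoffs are
re-derived per folding backend, so the literature bound of 0.41 does not
apply here); r_signature ≈ 4 means the family's trinucleotide signature
occurs about 4 times per 100 nt of the precursor window. Scoring the
predictions against the read library and the known matures:

```bash
mirsig validate --predictions run/predictions.tsv \
                --reads fixtures/reads.fasta \
                --known fixtures/queries.fasta --out val
# 1/5 predictions confirmed by reads
# tp=3 fp=2 fn=16
```

Three predictions reproduce known mature sequences exactly; the two
"false positives" are miRNA*-arm predictions — sequences recovered from
the opposite hairpin arm that are not in the query set.

`mirsig catalog` and `mirsig cutoffs` expose the two reference-building
steps separately (signature catalog TSV, cutoff JSON).

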