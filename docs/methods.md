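# Methods

`mirsig` predicts plant pre-miRNA hairpins and their mature miRNAs by
combining homology to known mature miRNAs with a seven-criterion filter
built from RNA-folding descriptors and family-specific simple sequence
repeat (SSR) signatures. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic test bed does
and does not demonstrate.

## The prediction model

A candidate precursor is any window of a subject sequence (EST, GSS or
genomic fragment) that contains an ungapped homolog of a known mature
miRNA. Candidates are accepted when all seven criteria hold:

1. the window folds into a hairpin with negative minimum free energy and
   MFEI at or above the acceptance bound;
2. the mature sequence sits on one arm of the stem, outside the terminal
   loop;
3. the mature pairs its miRNA* partner with fewer than 6 mismatches
   (mature length minus mature positions paired outside the mature);
4. the miRNA* is unbroken — no position inside the star span pairs
   outside the mature span;
5. AU content lies inside the acceptance range;
6. the ensemble descriptors NQ and ND lie at or below, and the pairing
   propensity Npb at or above, their bounds;
7. the query's miRNA family has an SSR signature and the window carries
   it at density R ≥ 2.5 per 100 nt.

When several windows of one homology hit pass all seven, the window with
maximal MFEI, then maximal R, then (for determinism) the shortest length
and smallest start coordinate is selected. Identical mature sequences
within a family collapse into one prediction; suffix letters (a, b, …,
z, aa, …) are assigned in sorted-sequence order so naming never depends
on input order.

## Descriptors

For a window of length L with MFE structure energy `MFE` and ensemble
pair probabilities `p_ij`:

- `AMFE = -MFE / L × 100` (kcal/mol per 100 nt),
- `MFEI = AMFE / (G+C)%` with GC on the percent scale (50, not 0.5) —
  undefined when GC = 0, in which case criterion 1 fails,
- `NQ = -(1/L) Σ_{i<j} p_ij log2 p_ij` (bits per nt),
- `ND = (1/L) Σ_{i<j} p_ij (1 - p_ij)` (per nt),
- `Npb = pairs in the MFE structure / L` ∈ [0, 0.5].

Acceptance bounds are the empirical 99%-probability region of a
reference precursor population: central intervals (quantiles at 0.005
and 0.995, linearly interpolated order statistics) for length and AU%,
single-tail quantiles for the one-sided quantities (MFEI and Npb at the
1st percentile, NQ and ND at the 99th). Boundary values pass. The
literature bounds (length 55–505 nt, AU 22–77%, MFEI ≥ 0.41, NQ ≤ 0.45,
ND ≤ 0.15, Npb ≥ 0.25) are shipped as a named constant; they presuppose
a full thermodynamic folder, so when the built-in model is used the
bounds must be re-derived from a reference population folded with the
same engine — MFEI in particular is energy-scale dependent. Two printed
variants of the AU range exist (22–77% and 27–77%); the former is the
default and the latter is available as a second constant.

## The folding engine

The default engine is a deliberately simple, exactly solvable base-pair
energy model: GC = −3.0, AU = −2.0, GU = −1.0 kcal/mol per pair, minimum
hairpin loop 3 nt, no stacking or loop terms. Three consequences matter:

- The MFE structure is computed by interval dynamic programming; ties
  are broken toward fewer pairs, then the lexicographically smallest
  dot-bracket, making output fully deterministic.
- Pair probabilities come from the Boltzmann partition function
  (weights `exp(-E/RT)`, RT = 0.616 kcal/mol) via an inside recursion
  and its algorithmic adjoint — the reverse-mode sweep of the inside
  computation, which is exactly the McCaskill outside pass — so
  `p_ij = q_ij ∂Z/∂q_ij / Z` is exact. The partition function is scaled
  per position (anchored at the MFE) to stay inside double precision;
  the scale cancels in the ratio. Probabilities below 1e-9 are dropped
  from the sparse map; their contribution to NQ/ND is far below the
  quantile resolution of any cutoff.
- Because every feasible pair lowers the energy, the model maximizes
  pairing wherever geometry allows. Real thermodynamic folders penalize
  loops; this one does not. All descriptor scales (MFEI ≈ 1.4 rather
  than ≈ 1.0, larger NQ) are therefore model-specific, which is exactly
  why cutoffs are re-derived per backend.

Both the MFE and the probabilities are validated against an exhaustive
structure enumerator (kept in the package as the independent reference
path) on random sequences up to 18 nt, at 1e-9 tolerance. The engine is
pluggable: any object with `fold(seq) -> FoldingProfile` can replace it,
e.g. an adapter around an external thermodynamic folder; the contract is
tested with a mock backend. Hot loops are numba-compiled; the first fold
in a process pays a one-off JIT cost of a few seconds.

## Homology model

Mature miRNAs are 15–24 nt, so homology is modeled as ungapped
full-query alignment: a hit is any placement on either strand with at
least one exact 7-mer seed and at most 3 mismatches overall. No
alignment statistics (e-values) are computed — at the permissive
thresholds this protocol historically used, the seed and the mismatch
bound are the only operative filters. Externally computed 12-column
tabular hits can be ingested instead. The scanner is verified against a
brute-force all-offsets Hamming scan.

Candidate windows of every length in [55, 505] nt (configurable) that
contain the full hit are enumerated; a stride parameter steps both the
length and the offset grid for large inputs (stride 1 = exhaustive).

Coding exclusion: a candidate is discarded when any of its six
reading-frame translations aligns ungapped to a supplied protein at
≥ 80% identity over ≥ 20 residues. Identity is evaluated over sliding
20-residue diagonal windows; a longer, barely-qualifying segment with no
qualifying 20-residue window would in principle be missed, but such
segments do not arise from the exact-copy decoys this filter is tested
against. Inside the pipeline the subject is scanned once and windows are
rejected by span containment, which is equivalent to filtering windows
individually.

## SSR signatures

R = (motif occurrences / L) × 100, with occurrences counted at every
overlapping start position. A family's signature is the 3-mer present in
all members with the highest average R (lexicographic tie-break);
single-member families take their maximum-R 3-mer. Signatures below
average R 2.5 are treated as absent unless the threshold is disabled.
Window sizes 4–6 are supported by the counter, but catalogs default to
3-mers — at larger windows few families retain a conserved signature. An
optional tandem-only counting mode (motif occurrences inside perfect
runs of ≥ 2 units) exists for sensitivity analysis; occurrence counting
is the default reading.

## Synthetic study design

The generator plants an idealized hairpin: 5' flank + mature + loop +
reverse-complement star + 3' flank. Defaults: mature 21 nt, 2 planted
stem mismatches (star-side substitutions chosen to unpair their
partner), loop 8 nt, flanks 15 nt, GC bias 0.5, three non-overlapping
copies of the family signature motif written into the flanks. Because
the pair-maximizing model recruits free bases into alternative stems,
the generator folds each draw and redraws (deterministically under its
seed) until the planted geometry is realized in the MFE structure;
a handful of draws usually suffice.

The full study (mirrored by `scripts/acceptance.py` and the acceptance
tests) uses:

- a reference population of 1000 hairpins with randomized geometry
  (mature 19–24 nt, loop 6–12, flanks 10–25, GC bias 0.35–0.65) for
  cutoff derivation;
- 25 known families of 1–4 members each (catalog + queries);
- 20 planted ESTs: a new hairpin carrying a known family's mature
  sequence and that family's derived signature motif, embedded in random
  DNA flanks (60–160 nt), ~30% on the minus strand. The derived (not
  raw) signature is planted because the motif that wins a family's vote
  can be a chance repeat, and a true homolog carries whatever signature
  its family actually has;
- 200 decoys: 60% random DNA, 20% dinucleotide shuffles of the planted
  subjects (Altschul–Erickson shuffling, preserving exact dinucleotide
  counts), 20% random DNA embedding a reverse-translated 30-residue
  protein stretch that must trip the coding filter;
- a collapsed read library supporting ~70% of the query matures, plus
  noise reads and sub-14-nt fragments that the length filter must drop.

Pipeline settings for this study: window lengths 55–125 at stride 3,
matching the ~80-nt scale of the generated precursors while keeping the
window grid dense enough that every hit retains many candidate windows.

What passing shows — and does not. The synthetic study exercises every
pipeline stage with known ground truth: strand handling, coordinate
arithmetic, criterion logic, selection, naming, dedup, and the
self-consistency of cutoff derivation. It does not show that the
built-in energy model discriminates real plant pre-miRs from genomic
background: planted hairpins are thermodynamically idealized, decoys
carry no hairpin mimics, and EST flanks are uniform random. Claims about
real-data performance require a thermodynamic backend and re-derived
cutoffs.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; 1-based
  inclusive only at format boundaries (BLAST tabular input, FASTA/TSV
  output).
- T→U on ingest for all RNA-role sequences; subjects stay as given but
  are compared in U-space.
- G:U wobble counts as a pair both in folding and in duplex mismatch
  counting.
- "No loop or break in the miRNA*" is operationalized as star
  contiguity: no position inside the star span pairs outside the mature
  span. A mature with no external partners has no locatable star and
  fails both the one-arm and the contiguity criteria.
- Duplex mismatches count mature-side unpaired (or self-paired)
  positions only; bulged star-side nucleotides are not counted
  separately.
- The mature/star criterion is enforced locally (one stem, outside the
  terminal loop) rather than demanding the whole window be a single
  unbranched hairpin — real precursor windows have structured flanks.
- Selection order MFEI before R; remaining ties by window length then
  position.
- Collapsed-read headers use the `<id>_x<count>` convention; plain FASTQ
  is collapsed on the fly. A header without a parseable count warns and
  counts 1.
- TPM uses the cleaned (length-filtered) library total by default.
- Read support requires full-length exact identity by default; a
  mismatch allowance is exposed. Known-set matching is exact mature
  identity, with an optional small 5'/3' end-offset slack.
- Specificity/NPV require a caller-supplied candidate universe for the
  true-negative count; they are reported as undefined (None), never 0,
  when a denominator is empty.

## Known limitations

- The built-in energy model has no stacking, loop penalties, or dangles;
  it is an exactly solvable stand-in whose cutoffs are self-consistent
  but not transferable to thermodynamic folders.
- Gapped homology (indels between query and subject) is not modeled.
- The coding filter's sliding-window identity is slightly stricter than
  a maximal-segment identity for marginal alignments.
- Window enumeration at stride 1 over the full 55–505 range is
  exhaustive and correspondingly expensive; the stride knob trades
  fidelity for speed.
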