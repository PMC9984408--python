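# Methods

## Scope and data flow

`beamplicon` quantifies base-editing outcomes from single-end (or pre-merged)
amplicon reads against a declared target geometry, and separately filters
RNA-seq variant tables for guide-independent deaminase off-targets. Upstream
read generation (sequencer, demultiplexing, paired-end merging) and upstream
RNA-seq processing (alignment, variant calling) are out of scope: the package
consumes FASTQ plus a target configuration on the DNA side, and
VCF/TSV variant tables on the RNA side.

## Target geometry

A target is an amplicon reference plus a protospacer and PAM (IUPAC-aware,
e.g. NGG). The protospacer must occur exactly once, on either strand, with
its PAM immediately 3' on that strand; zero or multiple PAM-flanked
occurrences are errors. Positions are numbered 1..L from the PAM-distal 5'
end of the protospacer (the PAM is not numbered), and this numbering is
strand-invariant: for minus-strand targets the position map runs backwards
along the top strand and observed bases are complemented into protospacer
orientation before any counting. Amplicon coordinates are 0-based half-open
throughout.

## Adapter trimming

Library adapters are constant PCR-primer tails (forward
`GGAGTGAGTACGGTGTGC`, backward `GAGTTGGATGCTGGATGG`). Trimming is exact
substring matching, plus end-anchored partial matches of at least
`min_overlap` (default 8) bases: a suffix of the forward adapter at the read
start, or a prefix of the reverse-complemented backward adapter at the read
end. Everything outside the insert is removed, qualities in lockstep. Exact
matching (0 mismatches) keeps the operation deterministic and
oracle-testable; adapters are constant sequence, so tolerance buys little.

## Alignment

Reads are aligned semi-globally: the read is global, the amplicon's
unaligned flanks are free, gaps are affine with cost
`gap_open + L*gap_extend` (defaults +2/−1 match/mismatch, −6/−1 open/extend).
The dynamic program is Biopython's `PairwiseAligner`; among co-optimal
alignments the first reported one is used, which is deterministic for fixed
inputs. Reads failing mean Phred ≥ 20, length ≥ protospacer length, score ≥
0.6 of the maximum, or not spanning the protospacer are counted `unusable`
(never as indels). The test suite checks scores against an independently
written straight-line Gotoh DP on random instances.

## Per-position quantification

- Indel window: protospacer ± 5 nt. Reads with any insertion or deletion
  overlapping it increment `n_indel` and are excluded from base counts.
- Among indel-free reads, every protospacer position accumulates the
  observed base (A/C/G/T/N, protospacer orientation); per position the
  counts sum to `n_indel_free`.
- Efficiency of conversion X→Y at position i is defined only where the
  reference base is X; other positions are NaN, never 0. N calls are
  removed from numerator and denominator.
- Indel frequency is `100·n_indel/n_aligned` — a different denominator from
  substitutions, deliberately, so gap columns cannot deflate conversion
  rates while indels are still reported against all aligned reads.

## Allele statistics

An allele is the read's protospacer-window sequence (deleted columns `-`),
plus an indel flag. Classification into six exclusive classes: indel first;
then simultaneous (≥1 qualifying A→G **and** ≥1 qualifying C→T), only-A→G,
only-C→T; then other-substitution; else unedited. Qualifying positions
default to every reference A (resp. C) in the protospacer — the most
inclusive reading of "simultaneous A/C conversion" — and are restrictable to
windows. Stray substitutions do not demote an allele that carries a
qualifying edit. Indel alleles stay in the denominator of the simultaneous
fraction (they simply can never qualify). "Mutant allele types" counts
distinct non-reference alleles above a frequency floor (default 0.1% of
reads) because without a floor the statistic is dominated by
sequencing-error singletons.

## Editor comparison

Inputs are per-site (or per-replicate) × per-position efficiency matrices.
Per position: fold change of cross-row means (undefined, reported NaN, when
the denominator mean is 0 — never raised) and a two-tailed two-sample
t-test. Per window: per-row means over editable positions, compared with a
two-sided **paired Wilcoxon signed-rank** test — our reading of a "paired
rank-sum" test, since pairing makes the rank-sum construction the
signed-rank one. The signed-rank implementation drops zero differences
(all-zero ⇒ p = 1.0 by convention), uses midranks for ties, an exact null
for ≤ 25 nonzero pairs via generating-function convolution on the doubled
rank lattice, and a tie-corrected normal approximation with continuity
correction beyond that. No multiple-testing correction is applied anywhere;
reports state this.

## RNA off-target filtering

Thresholds (all configurable): coverage percentile 90 (linear-interpolation
/ type-7 percentile, fixed for determinism), control reference consensus
0.99, GFP minimum 10 reads with > 0% alternate reads. The chain: (1) a
candidate locus is kept iff the control depth at that locus **exceeds** the
90th percentile of the overexpression sample's variant coverages and the
control reference fraction is ≥ 0.99 (loci absent from the control are
excluded); (2) loci matching a GFP-control editing event on
(contig, position, ref, alt) are subtracted; (3) survivors are labeled
A-to-I (A>G on +, T>C on −), C-to-U (C>T on +, G>A on −), else `other`
(unknown strand ⇒ `other`). The percentile rule compares control coverage
against the overexpression coverage distribution — implemented literally as
stated, though the underlying intent (depth matching) is not documented in
the field's descriptions. Boundary semantics are strict where the wording
is strict: control depth equal to the percentile fails; ref fraction
exactly 0.99 passes; GFP depth 9 is not background, depth 10 with ≥ 1
alternate read is.

## Synthetic data generator

The read simulator emulates an edited cell population sequenced by amplicon
HTS. Per read: edits are drawn either from one shared uniform draw
(probability `rho`) — comonotone coupling, co-edit frequency → min of
marginals — or independently per position (probability `1−rho`, co-edit
frequency → product). Marginals equal `p_edit` exactly for every `rho`.
This two-component mixture was chosen because it has closed-form marginals
and spans independence to full coupling with a single parameter. Indels
(signed-size distribution, default mostly 1–3 nt deletions) are placed
uniformly **within the protospacer span**; the ±5 nt quantification pad then
absorbs leftmost gap shifts under alignment ambiguity, which keeps the
truth table and the re-quantified calls consistent (an indel planted at the
pad edge can otherwise be realigned just outside the window). Sequencing
errors are uniform substitutions at a flat rate with constant Phred — no
quality-dependent or indel-error model, and no PCR-duplicate or realistic
Illumina profile; green simulator-based tests therefore establish estimator
correctness under the stated model, not robustness to real error profiles.
All draws flow from one seeded NumPy generator: fixed seed ⇒ byte-identical
output.

The RNA-table simulator plants true edits (strand-consistent A-to-I by
default) with clean deep controls, heterozygous background SNPs (fail the
consensus gate), and GFP-background loci (removed by subtraction). Control
depths at clean loci are drawn from a range (default 500–1000) above the
overexpression depth range (default 20–200), so planted edits pass the
percentile gate by construction; the recall-1/FP-0 property states the
generator's world, not a tuned outcome.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| adapter `min_overlap` | 8 nt | below ~7 nt random suffix matches become likely |
| QC mean Phred / score fraction | 20 / 0.6 | permissive read filter; explicit because the convention varies between tools |
| scoring | +2/−1, gaps −6/−1 | standard short-read scale; deterministic tie handling |
| indel window pad | ±5 nt | nick-centered window, standard practice |
| allele-type frequency floor | 0.1% | suppresses error singletons |
| simulator `n_reads` | 5000 | binomial SE < 1% for mid-range rates |

## Known limitations

- No paired-end merging, demultiplexing, UMI handling, or quality-aware
  probabilistic base calling.
- Alignment tie-breaking follows Biopython's deterministic enumeration
  order rather than an explicit mismatch-over-gap preference; scores are
  identical, and only gap placement within co-optimal alignments can differ.
- Allele classes are computed over the full protospacer window; large
  rearrangements or edits outside the amplicon are invisible.
- The RNA stage trusts the upstream caller's depths; it performs no
  realignment or base-quality reassessment.
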