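# Methods

## Coordinates and data model

All intervals are 0-based half-open (BED convention) everywhere inside
the package; SAM and Bismark inputs are shifted on read. A full-length
L1 locus is a strand-annotated interval of ≥ 5,500 bp (configurable)
with a subfamily label and an externally supplied intact-ORF2 flag. The
promoter anchor is the strand-resolved 5′ end of the element — `start`
on the plus strand, `end` on the minus strand — which makes every
"upstream/downstream of the 5′UTR start site" window computable on both
strands through a single `strand_window` primitive. Overlap is always
edge-to-edge intersection of half-open intervals (≥ 1 bp shared).

## Expression calling

A read pair is reduced to one fragment spanning the outermost mate
coordinates; its transcription strand is read 1's strand (stranded FR
library). Only concordant pairs (properly paired, one chromosome) are
counted, because authentic L1 mRNA is unspliced and should align as an
intact genomic fragment. A fragment counts for a locus iff it overlaps
the locus body on the matching strand; each fragment is assigned to at
most one locus — largest overlap wins, ties go to the leftmost locus —
so summed counts never exceed the number of concordant fragments.

Depth normalization multiplies counts by *f* = N_ref / N_sample,
reported and applied at two decimals, with half-away-from-zero rounding
of the scaled counts (the rounding rule is stated explicitly because
ties at .5 are otherwise implementation-defined). Reads-per-million on
the sample's own depth is carried alongside.

Curation automates the visual check that reads originate from the L1
promoter rather than an upstream one. A locus with ≥ 1 counted fragment
passes iff

1. the fraction of counted fragments whose strand-aware 5′ end lies in
   the first 900 bp of the element is ≥ 0.5, and
2. mean per-bp coverage over the 1 kb strand-aware upstream flank is
   ≤ 0.5 × mean coverage over the first 900 bp.

Both thresholds are configurable; the defaults were chosen once as the
minimal mechanical reading of "originates from the L1 promoter". The
flank criterion deliberately uses all fragments on the chromosome, not
only counted ones, so upstream transcription that never touches the
element still disqualifies it. Zero promoter coverage with non-zero
flank coverage counts as an infinite ratio (fail); zero/zero passes.

Classes: 0 reads → unexpressed; 1..threshold−1 → potential modest;
≥ threshold and curation pass → expressed; ≥ threshold and fail →
passive transcription. The threshold applies to the normalized count,
with *f* = 1 for the reference library itself. Defaults are 20 reads,
9 for a roughly half-depth library, and 5 in stimulation mode
(re-analysis of activation experiments). Downsampling (uniform subset
without replacement, seeded) reproduces the robustness check that deep-
library expression calls survive matching a shallower library's depth.

## Promoter epigenetics

- **ATAC**: positive iff any peak intersects the symmetric window
  [anchor − 500, anchor + 500). The direction of "within 500 bp" is not
  specified by the underlying protocol description, so the symmetric
  interval is used as the minimal reading; the histone windows below are
  explicitly directional. The best overlapping peak score is kept for
  ranking transitional loci.
- **Histone marks**: each track (six activating marks × two replicates,
  12 tracks; 6 in reduced panels) contributes at most 1 if it has a peak
  in the strand-aware window 500 bp upstream to 300 bp downstream of the
  anchor. The per-locus count is reported with the panel size; it is
  invariant to track order.
- **CpG methylation**: over the first 500 bp of the 5′UTR (from the
  anchor into the body, strand-aware), a covered CpG is methylated when
  its methylated fraction is ≥ 0.5, and the locus summary is
  100 × methylated / covered. Uncovered CpGs never count as
  unmethylated; a locus with no covered CpG has undefined methylation
  and is excluded from group means. A weighted mode (mean methylated
  fraction) is available behind a flag.
- **Gene overlap**: strand-agnostic ≥ 1 bp intersection of the body with
  any gene interval.

The feature-table join emits one row per catalog locus with explicit NA
for missing inputs and rejects duplicate locus ids.

## Categories and L1Hs context prediction

*Expressed* requires the expression class; *transitional* is zero raw
reads with an ATAC peak (open chromatin poised for activation);
*unexpressed-closed* is zero reads without a peak; everything else
(passive, modest) is *other*. For poorly mappable L1Hs copies the
context rule is: no ATAC peak → unlikely expressed (hard gate, never
overridden); ATAC peak with mark count ≥ half the panel and methylation
≤ 50% (or unknown) → likely expressed; otherwise indeterminate. The
mark and methylation cut-offs operationalize a qualitative judgement and
are configurable; ATAC as the dominant gate reflects its order-of-
magnitude discrimination between candidate sets. Read-through counting
adds a strand-aware 2 kb 3′ extension to the locus body to capture
poly-A read-through into mappable sequence.

## Mate-anchored L1Hs detection

Stage 1 aligns each mate of every WGS pair to the L1 consensus
(ungapped, both orientations, ≤ 25 mismatches, unique best strictly
better than second best). Mates starting within the first 700 bp of the
consensus in reverse orientation point out of an element's 5′ end.
Stage 2 aligns the partner mate to the genome (≤ 3 mismatches, unique).
Stage 3 intersects the partner's interval with the 1 kb strand-aware
upstream window of each annotated L1Hs locus; the upstream window size
is not fixed by any convention and defaults to 1,000 bp, with partner
alignments treated as intervals. A locus is reported with its
supporting-pair count (minimum support 1, configurable).

The aligner is an exhaustive-equivalent ungapped Hamming scan. On
references too long for a direct scan it uses a pigeonhole seed filter:
with k = ⌊read_length / (max_mm + 1)⌋, any placement within the
mismatch cap contains at least one exact disjoint k-mer, so a rolling-
hash scan of the reference against all read seeds enumerates the
complete candidate set, which is then verified by Hamming distance. The
strict-uniqueness decision is unaffected, because any unseen placement
must exceed the cap and is therefore strictly worse than a within-cap
best. This is a desk-scale tool for references up to a few tens of Mb,
not a production aligner; gapped alignment and quality scores are out of
scope.

## Regulatory context

A promoter is inside a CTCF loop when it lies between the two anchors
and both anchors are within 500 kb (point-to-interval distance). A Pol
II loop is associated when its nearer anchor overlaps the ±500 bp
promoter window; the other anchor is the putative enhancer (the more
distal anchor when both overlap), with ties among loops resolved by
higher score then smaller span. Enhancer mark count is the number of
tracks with a peak intersecting the enhancer interval, unpadded; no
enhancer means zero by convention. These interval rules are declared
conventions replacing visual browser interpretation of ChIA-PET data.
The summary additionally reports group tallies ("Yes (7/10)": majority
label with the yes-count) and mean ± sample (n−1) standard deviation of
reads and mark counts. Top-group selection ranks expressed loci by
normalized reads, transitional by ATAC peak score, and draws unexpressed
loci uniformly at random with a fixed seed.

Motif status of the YY1 (`AGCCAAGATGGCCGAATAG`) and RUNX3
(`TGCATTTCCATCTGAGGTA`) promoter sites is the minimum-Hamming placement
of the motif in the promoter sequence (leftmost on ties): 0 mismatches →
consensus, 1–6 → mutated, > 6 → deleted. The deletion threshold stands
in for gap-aware alignment, which is out of scope; sequences shorter
than the motif are reported deleted.

## Statistics

The 2×2 chi-square uses Yates' continuity correction,
χ² = n(|ad − bc| − n/2)² / (r₁r₂c₁c₂) truncated at zero, df = 1, and is
undefined (error) on zero marginals. The t-test is two-sided
pooled-variance Student's t (a Welch option exists behind a flag);
degenerate zero-variance input yields p = 1 for equal means and p = 0
flagged by an infinite statistic otherwise. Pearson p-values come from
the t-transform with n − 2 df. Standard deviations are sample (n − 1)
throughout; percentages are rounded half-away-from-zero to two
decimals, means reported at one decimal in summaries. p-values are
reported raw, with no multiple-testing correction. The test suite
verifies the chi-square and t implementations against an independent
reference implementation to six significant digits.

## Synthetic data generator

The generator emulates the per-class statistical structure of the
real assays on one synthetic chromosome (default 10 Mb, 600 loci of
6 kb placed without overlap in evenly spaced jittered slots, ≥ 3 kb
clearance). Class proportions default to 3.3% expressed, 6%
transitional, 1% passive, remainder closed. Every locus body is a
mutated consensus copy (0.5% divergence for L1Hs, 5% for older
subfamilies), so promoter motif scanning and junction simulation use
realistic sequence. Defaults, chosen once as the validated study
conditions:

- **Counts**: expressed and passive loci draw fragment counts from a
  negative binomial with mean 71.2; the dispersion parameter φ = 0.5 is
  interpreted as quasi-likelihood overdispersion, var = (1 + φ)·mean,
  i.e. a modestly overdispersed Poisson. Expressed fragments start
  uniformly in the first 900 bp of the element; passive fragments
  originate 200–2,500 bp upstream and read through into the body;
  background fragments are confined to inter-locus gaps.
- **ATAC**: class probabilities 0.8272 (expressed), 0.03 (closed), 0.2
  (passive); transitional loci are ATAC-positive by construction.
- **Marks**: per-track Bernoulli probabilities giving expected counts of
  ≈ 5.91/12 (expressed) and ≈ 0.21/12 (closed), with intermediate
  values (0.25, 0.10 per track) for transitional and passive loci.
- **Methylation**: 10 promoter CpGs per locus; each CpG is methylated
  with the class probability (0.3626 expressed, 0.6082 closed/passive,
  0.45 transitional) and its read-level fraction is drawn from a high
  (mean 0.9) or low (mean 0.1) beta with concentration 5 — a bimodal
  model, so the binarized percent-methylated centres on the configured
  class mean. Coverage is 1 + Poisson(19); 2% of promoters are left
  uncovered to exercise the exclusion rule.
- **Loops**: CTCF loops span 90% of loci with anchors 50–400 kb away;
  Pol II loops attach to promoters at class rates 0.9 / 0.4 / 0.1
  (expressed / transitional / other), with enhancers 20–100 kb away
  that are mark-rich (10–12 tracks) for 80% of expressed-locus loops.
- **WGS pairs**: for each of 20 truly present L1Hs loci (20 more are
  annotated but absent from the sample), 10 pairs pair a reverse-
  oriented read from the first 550 bp of the consensus with a genomic
  read from the 1 kb upstream flank; 100 decoy pairs come from gaps;
  bases are substituted at 1%.

Randomness flows from a single seed through per-stage substreams
(stage-index + seed keys into `numpy`'s seed sequence), so regenerating
one stage never perturbs another and fixed seeds give byte-identical
files.

What the generator does **not** model: real mappability structure (the
synthetic genome is random outside the planted elements, so unique
alignment is easier than in a genome full of diverged repeats), splice
products and transcript structure, sequencing quality profiles and
indels, peak-width and signal distributions of real MACS2 output, CpG
density variation, and inter-locus correlation of chromatin state.
Passing tests therefore demonstrate the correctness and calibration of
the pipeline's logic under the stated statistical structure, not
performance on real libraries.

## Problem sizes and determinism

The default validation runs use 600 loci on a 10 Mb chromosome
(~2,500 fragments, ~300 WGS pairs, 13 peak tracks), for which the whole
pipeline plus detection completes in seconds; scaled-down configurations
(30–40 loci on ~1.5 Mb) back the per-stage unit tests. All entry points
accept explicit seeds, and report generation is byte-deterministic for
fixed inputs.

## Known limitations

- Curation thresholds (0.5/0.5, 900 bp) are heuristics standing in for
  expert judgement; loci with mixed promoter/read-through signal near
  the thresholds are sensitive to them.
- The ATAC window's symmetry and the 1 kb L1Hs upstream window are
  declared conventions; both are parameters, and sensitivity analysis is
  left to the user.
- The L1Hs context prediction is a rule, not a fitted classifier, and
  inherits the arbitrariness of its mark/methylation cut-offs.
- The motif scan is substitution-only; partial deletions smaller than
  the threshold are reported as mutations.
- Single-end data, CRAM/BAM random access, peak calling, liftover and
  gap-aware alignment are out of scope.
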