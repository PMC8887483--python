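# l1context

Locus-resolution analysis of which full-length LINE-1 (L1) elements are
expressed, and of the epigenetic and 3D-genomic context that permits their
expression.

Full-length L1 retrotransposons carry an internal RNA Pol II promoter in
their ~900 bp 5′UTR. Most of the several thousand full-length copies in a
human genome are silent; a small subset drives the L1 mRNA that matters
for retrotransposition and genome instability. `l1context` is for
genomicists who want to move from bulk "global L1 expression" readouts to
per-locus calls: which individual elements are transcribed from their own
promoter, which sit in open chromatin poised to fire, and which are shut
down — and how ATAC accessibility, activating histone marks, promoter CpG
methylation, CTCF/Pol II loops and promoter motifs separate those states.

## What it computes

Given a BED6+ catalog of full-length L1 loci (≥ 5,500 bp), stranded
paired-end RNA-seq fragments (BEDPE or SAM), peak tracks (broadPeak/BED),
per-CpG methylation counts, ChIA-PET loops (BEDPE) and WGS read pairs:

- **Expression calling.** A fragment counts for a locus iff it is
  concordant, sense-strand and overlaps the body ≥ 1 bp (single
  assignment; largest overlap, then leftmost). Counts are depth-normalized
  by the library-size ratio *f* = N_ref / N_sample (reported at 2
  decimals; counts rounded half-away-from-zero) and thresholded
  (defaults: 20 reads, 9 for low-depth libraries, 5 in stimulation mode).
  Automated curation replaces visual inspection of alignments: a locus
  passes when ≥ 50% of its fragments start within the first 900 bp of the
  element and upstream-flank coverage ≤ 0.5 × promoter coverage;
  threshold-passing loci that fail are *passive transcription*
  (read-through from an upstream promoter).
- **Promoter epigenetics.** ATAC association within ±500 bp of the
  strand-aware 5′UTR start site; activating-mark count over a 12-track
  panel (H3K27Ac, H3K9Ac, H3K4Me3/2/1, H4K20Me1 × 2 replicates) in a
  −500/+300 bp strand-aware window; percent methylated CpGs (per-CpG
  fraction ≥ 0.5) over the first 500 bp of the 5′UTR, covered CpGs only.
- **Categories.** *expressed* / *transitional* (zero reads but an ATAC
  peak) / *unexpressed-closed*, plus context-based prediction of which
  poorly mappable L1Hs copies are likely expressed (ATAC gate + mark and
  methylation thresholds).
- **Mate-anchored L1Hs detection.** One WGS mate anchored in reverse
  orientation within the first 700 bp of the L1 consensus (≤ 25
  mismatches, unique), its partner placed uniquely on the genome (≤ 3
  mismatches) and intersected with the 1 kb strand-aware upstream window
  of annotated L1Hs loci.
- **Regulatory context.** CTCF-loop containment (500 kb search), Pol II
  loop → enhancer assignment (±500 bp promoter window, distal anchor =
  enhancer), activating marks on enhancers, YY1/RUNX3 promoter motif
  status by Hamming scan, and Table-style group summaries.
- **Statistics.** 2×2 chi-square with Yates' correction, pooled-variance
  Student's t, Pearson correlation, and report generation
  (class counts, percent-ATAC / marks / methylation per class, L1Hs
  group contrasts).

A seeded synthetic-data generator (`l1context.simulate`) produces every
input with ground-truth labels, so the whole pipeline is testable without
any external dataset.

## Worked example

```python
import l1context as lc

sim = lc.simulate(lc.GeneratorConfig(seed=1))          # 600 loci, 10 Mb
table = lc.run_pipeline(
    sim.loci, sim.fragments,
    atac_track=sim.atac_track,
    histone_tracks=sim.histone_tracks,
    meth_records=sim.meth_records,
    loops=sim.loops,
    threshold=20,
)
print(table["epigenetic_class"].value_counts().to_string())

expressed = table[table["epigenetic_class"] == "expressed"]
closed = table[table["epigenetic_class"] == "unexpressed_closed"]
me, mc = (g["meth_percent"].dropna().astype(float) for g in (expressed, closed))
t, p, ma, mb = lc.t_test(me, mc)
print(f"methylation: {ma:.2f}% vs {mb:.2f}%  (t = {t:.2f}, p = {p:.3g})")

hits = lc.detect_l1hs(sim.wgs_pairs, sim.consensus, sim.genome, sim.loci)
print("L1Hs detected:", len(hits))
```

prints

```
epigenetic_class
unexpressed_closed    520
transitional           52
expressed              25
other                   3
methylation: 34.40% vs 60.06%  (t = -8.31, p = 7.99e-16)
L1Hs detected: 20
```

25 loci are called expressed (all 25 truly expressed loci; the 3 "other"
are passive read-through loci correctly rejected by curation), 52 are
open-but-silent transitional candidates, expressed promoters are strongly
hypomethylated relative to closed ones, and all 20 L1Hs copies planted in
the simulated sample genome are recovered by mate anchoring with no false
positives.

The same stages are available from the shell:

```bash
l1context simulate --out sim/ --seed 1
l1context features --catalog sim/catalog.bed --fragments sim/fragments.bedpe \
    --atac sim/atac.broadPeak --methylation sim/methylation.tsv \
    $(for f in sim/marks/*.broadPeak; do echo --marks $f; done) --out features.tsv
l1context classify --features features.tsv --out classified.tsv
l1context report --features classified.tsv --out report/
l1context detect-l1hs --pairs sim/wgs_pairs.tsv --consensus sim/consensus.fa \
    --genome sim/genome.fa --catalog sim/catalog.bed --out l1hs.tsv
```

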