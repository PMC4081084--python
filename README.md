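# peakscape

Downstream analysis of transcription-factor ChIP-seq peak calls: where does
a factor bind relative to genes, does that geography differ between active
and silent targets, which core-promoter elements sit under its summits, and
which other chromatin features co-occupy its sites?

`peakscape` was built around the binding geography of the general
transcription factor TFII-I in human K562 erythroleukemia cells — a factor
that binds both expressed and repressed genes, preferentially upstream of
the TSS at active genes but on both sides at silent ones — and packages
that analysis as a reusable, tested pipeline for any peak set:

* **annotate** — assign each peak (summit, else interval midpoint) to its
  nearest gene by absolute TSS distance; signed distances are strand-aware
  (negative = upstream of the TSS in the gene's reading direction); genic
  location is a five-way call (TSS / TES / intragenic / upstream /
  downstream) plus the intergenic roll-up.
* **stratify** — label target genes expressed (RPKM ≥ 1, inclusive) or
  silent and partition peaks into the six analysis classes: expressed /
  silent, proximal (|d| ≤ 1 kb) / distal, and proximal upstream / downstream.
* **stats** — Pearson 2×2 chi-square (χ² = N(ad−bc)²/(r₁r₂c₁c₂), df = 1),
  Wilcoxon rank-sum (exact enumeration for n+m ≤ 12 without ties, otherwise
  tie- and continuity-corrected normal approximation), Wilson score
  intervals, and an optional Benjamini–Hochberg utility.
* **motifs** — IUPAC consensus scanning (both strands, overlapping matches)
  of 75-nt summit-centered windows for the TATA box (TATAAA), initiator
  (YYANWYY), DPE (RGWYV), BRE (SSRCGCC) and the TFII-I/BEN site (RGATTR),
  with the census restricted to peaks within 1 kb of a TSS and the two BRE
  enrichment chi-square tests (proximal vs non-proximal; active vs silent).
* **cooccupancy** — percentage of each peak class overlapping external peak
  sets within a 150-nt gap tolerance, as a row-normalized matrix.
* **synthetic_data** — a generator that emulates the study's structure
  (strand-aware gene models, class-dependent TSS-offset distributions,
  planted motifs, conditionally co-occupying mark sets) and emits a
  ground-truth ledger, so the whole pipeline is testable without downloads.

## Worked example

```sh
peakscape simulate --seed 3 --out demo/sim
peakscape run --peaks demo/sim/tf_peaks.narrowPeak \
              --genes demo/sim/genes.tsv \
              --expr demo/sim/expression.tsv \
              --fasta demo/sim/genome.fa \
              --marks H3K4me3=demo/sim/marks/H3K4me3.narrowPeak \
              --out demo/out
```

prints

```
report: demo/out/report.json (2500 peaks, 300 genes)
```

and `demo/out/` then holds per-peak `assignments.tsv` and
`peak_classes.tsv`, the ±2 kb `tss_histogram.tsv`, `motif_census.tsv`,
`overlap_matrix.tsv` and a JSON report. With the default simulation the
report's `class_counts` equal the generator ledger's expected counts
exactly (seed 3 gives 1241 expressed / 1259 silent peaks, 1752 proximal /
748 distal, and 1161 upstream / 591 downstream among the proximal peaks),
the `downstream_abundance_chisq` p-value is 2.8e-24 — the planted upstream
bias of expressed-gene peaks is detected — and the H3K4me3 column of the
overlap matrix recovers the configured co-occupancy probability plus
background (87.7% of proximal peaks overlap a mark).

The same stages are available as library calls (`peakscape.simulate`,
`peakscape.run_analysis`, `peakscape.annotate_peaks`, …) for notebook use.

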