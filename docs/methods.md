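# Methods

This note documents the models, conventions and parameter choices behind
`peakscape`, the assumptions the synthetic-data generator makes, and the
limits of what the test suite demonstrates.

## Coordinate model

All coordinates are 0-based half-open (BED convention); GTF input (1-based
closed) is converted at the boundary. The TSS of a plus-strand gene is its
span start; for a minus-strand gene it is `span_end − 1`, i.e. the last
base of the span — the standard definition, stated here because nothing in
the interval alone disambiguates it. The TES is the opposite terminus.
narrowPeak summit offsets use the format's own convention, with the
sentinel −1 meaning "no summit"; peaks without summits fall back to the
floor midpoint everywhere a single reference point is needed.

## Nearest-gene assignment and distances

Each peak is reduced to one reference point — the summit when available,
since model-based peak callers localize binding most precisely there, else
the midpoint — and assigned to the gene minimizing the absolute TSS
distance on its chromosome. Signed distances follow the gene's reading
direction: `point − tss` on plus-strand genes and `tss − point` on minus,
so "upstream" always means 5′ of the TSS regardless of strand. Ties in
absolute distance break to the lexicographically smallest gene id, which
makes the assignment deterministic and independent of input order; peaks
on chromosomes without genes are reported as `unassigned` rather than
erroring. Genic location is a five-way classification with precedence
TSS > TES > intragenic > upstream/downstream: a peak interval containing
the TSS coordinate is a TSS peak even if it also lies inside the gene
span. An intergenic roll-up (upstream + downstream) is emitted alongside.

The queried index is a per-chromosome sorted-TSS array with binary search;
correctness, not the structure, is the contract, and the test suite pins
the indexed path to an exhaustive all-pairs oracle.

## Stratification

Expression labels come from an RPKM table thresholded at 1.0, boundary
inclusive (RPKM = 1 is expressed); genes absent from the table are
`unknown` and excluded from expressed-vs-silent testing, with an opt-in
mode that folds them into `silent` instead. Peaks inherit their assigned
gene's status. Proximity uses |d| ≤ 1 kb, again boundary inclusive — "±1 kb"
reads as a closed interval. Within the proximal set, orientation is the
sign of the distance; a distance of exactly 0 (summit on the TSS) counts
as downstream because transcription initiates inside the peak, and a
deterministic rule is required. All thresholds (1 kb proximal, ±2 kb
profile window, 100-bp bins, RPKM 1, 150-nt overlap gap, 75-nt summit
window, 1 kb census limit, 10 kb assignment limit) are configuration
parameters with these values as defaults.

The ±2 kb distance histogram uses half-open bins, with the numpy
convention that the final bin also accepts the right edge; densities are
per-class bin fractions.

## Statistics

* **Chi-square (2×2).** Closed-form Pearson statistic with df = 1,
  upper-tail p. Yates continuity correction is available but off by
  default — with the study-scale counts the correction is negligible, and
  the uncorrected statistic matches the closed form exactly. A zero
  marginal raises with advice to use an exact test.
* **Wilcoxon rank-sum.** For n + m ≤ 12 with no ties, the exact null
  distribution of the rank sum W is enumerated over all C(n+m, n)
  assignments; the two-sided p is P(|W − E W| ≥ |w − E W|). Otherwise a
  normal approximation with the standard tie correction of the variance
  and a 0.5 continuity correction is used; with the correction the exact
  and approximate p agree within 0.02 already at n = m = 6, and the null
  rejection rate at α = 0.05 is within ±0.01 of nominal (10 000-rep
  simulation in the acceptance suite). Which samples feed the two
  distance tests is configurable; the default is per-peak |distance|
  within the ±2 kb window, split by sign.
* **Proportions.** Wilson score intervals, used by the synthetic recovery
  checks; the degenerate counts 0/n and n/n return exact 0 and 1 bounds.
* p-values are reported raw (no multiplicity correction by default; a
  Benjamini–Hochberg helper exists). Text output prints p below the double
  floor as `< 2.2e-16` while the JSON keeps the raw float.

## Motif census

Scanning expands each IUPAC code into its base set and matches with an
overlap-tolerant regex; minus-strand hits are matches of the
reverse-complemented pattern reported at their plus-strand footprint
start. An `N` in the sequence matches only the pattern code `N`. Both
strands are scanned by default because peaks carry no orientation; a
plus-only mode exists. "A window of 75 nt around the summit" is
implemented as a 75-nt window centered on the reference point (±37),
clipped at chromosome ends with the clip logged; the width is
configurable for readings of that phrase as ±75. A peak counts for a
pattern when its window holds ≥ 1 match; multiplicity is reported
separately but never enters the fractions. The census classes are
expressed and silent peaks within 1 kb of the TSS, plus the expressed
subset split upstream/downstream; the BRE enrichment tests compare BRE
presence in proximal (≤ 1 kb) versus non-proximal peaks among all peaks
within 10 kb of a TSS, and in proximal peaks of active versus silent
genes.

The expected background rate of a literal 6-mer in a random 75-nt window
is ≈ 1 − (1 − 4⁻⁶)^k with k = 2·(75−6+1) scanned positions ≈ 3.4%; the
suite verifies the empirical rate within three standard errors.

## Co-occupancy

Two intervals co-occur when their edge gap is at most 150 nt, inclusive;
intersecting intervals have gap 0. This matches the gap semantics of the
standard overlapping-peaks utilities; a summit-distance mode (|summit
difference| ≤ maxgap) is provided behind a flag. Percentages are always
normalized by the TF class size, and each TF peak counts at most once
however many external peaks it touches. Queries run on per-chromosome
sorted starts with prefix-maximum ends (O((n+m) log m)); the test suite
pins this to the quadratic all-pairs scan. Empty classes yield flagged
undefined cells, not crashes.

## Synthetic data

The generator's defaults are the study conditions for every recovery
test:

| parameter | default | rationale |
|---|---|---|
| genome | 4 × 1.5 Mb, uniform ACGT | large enough for 300 genes at ≥ 2 kb spacing; uniform base composition keeps motif background analytic |
| genes | 300, lengths 2–10 kb, strands ±0.5 | non-overlapping with ≥ 2 kb spacing so nearest-gene truth is mostly unambiguous |
| expression | expressed ~ logN(median 10, σ=0.8) resampled ≥ 1; silent ~ logN(median 0.1) resampled < 1 | clean margin around the cutoff; an adversarial mode puts mass exactly at 1.0 to exercise the boundary rule |
| peaks | 2500, width 150–400 bp, 80% TSS-linked | 2500 × 0.8 × 0.5 ≈ 1000 linked peaks per expression class |
| offsets | expressed N(−300, 400); silent N(0, 800), truncated to ±10 kb | reproduces the qualitative upstream bias of active-gene binding, not any exact profile |
| motif planting | TATA 40%/10% (expressed/silent), BRE 30%/5% (proximal/distal) | strong enough for recovery within Wilson intervals at n ≈ 1000 |
| marks | H3K4me3 with q = 0.5, jitter ±100 bp, background 5 peaks/Mb | jitter below the 150-nt gap tolerance so every seeded mark is recovered |

Each artifact (genome, expression, peaks, motifs, marks) draws from its
own child stream of the master seed, so outputs are bit-for-bit
reproducible and independently regenerable. The ledger records, per peak,
the linked gene, realized offset and class, every planted motif position,
and — computed by an independent brute-force scan — the expected nearest
gene, distance and class labels; the expected class counts are derived
from the latter, because a large planted offset can legitimately place a
summit nearer a neighbouring gene than the one it was linked to. Motif
instances are planted uniformly inside the 75-nt summit window and never
overwrite one another (skipped with a log entry when no free slot
remains).

What the generator does **not** emulate: real peak-width and score
distributions, sequence composition bias (GC, repeats, CpG islands),
overlapping or nested genes, isoform structure, chromatin-state spatial
autocorrelation beyond single-mark seeding, and mapping artifacts.
Passing recovery tests therefore demonstrate the correctness of the
pipeline's bookkeeping and inference on data with known structure, not
robustness to those real-data complications.

## Problem sizes

The default simulation (2500 peaks, 300 genes, 6 Mb genome) runs the full
pipeline in a few seconds; the acceptance suite's power analysis uses 100
seeds of coordinate-only simulations (≈ 1 minute) and the null Wilcoxon
calibration 10 000 replicates at n = m = 20. These sizes give standard
errors comfortably inside every asserted tolerance while keeping the
whole suite fast to iterate on.

## Known limitations

* GTF parsing covers `gene` feature lines with a `gene_id` attribute —
  the dialect the package itself writes — not the full GTF zoo
  (transcript-level records are ignored by design; no GFF3).
* The nearest-gene rule is TSS-distance only; a gene-body-overlap notion
  of "nearest" would classify long-gene interiors differently.
* Exact Wilcoxon enumeration is limited to n + m ≤ 12; beyond that the
  corrected normal approximation is used even for moderately small
  samples.
* Percent shares in summaries round to integers and may sum to 100 ± 1.
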