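# Methods

## Study design assumptions

All analyses assume a time-series design keyed by cultivar × timepoint ×
replicate, with timepoints on an hours-post-entrainment (HPE) grid
(default 48–69 HPE, every 3 h — eight points covering most of one free-run
cycle after entrainment) and a fixed circadian period of 24 h. Expression
values are treated as abstract non-negative abundances (TPM-like); counts
(chromosome reads, variants) as non-negative integers. Internally every
genomic coordinate is 0-based half-open; GTF and variant tables keep their
standard 1-based inclusive conventions at the file boundary, which keeps
all interval arithmetic free of ±1 bookkeeping.

## Composite gene model and event classification

All isoforms of a gene are merged into one composite model: the exon union
(sweep-line interval merge) plus the pooled intron catalogue, each intron
tagged with its contributing isoforms. Events are called per isoform
against this composite:

* **IR** — an *internal* exon of the isoform strictly contains a catalogued
  intron contributed by a different isoform; one event per retained intron.
* **ES** — an intron of the isoform whose two ends coincide with exon
  boundaries of a sibling isoform, with ≥1 sibling exon strictly inside;
  the run of consecutively skipped exons is ONE event, `merged_count` = run
  length. Requiring the flank match is the standard skipping definition; it
  also prevents the exon-runs inside mutually-exclusive bubbles from being
  double-reported as skipping.
* **AA / AD** — two introns share their donor (5′ splice site on the
  transcription strand: intron start on `+`, intron end on `-`) and differ
  at the acceptor, or vice versa. Pairs whose difference region fully
  contains an internal exon of any isoform are excluded: such pairs are the
  junction-level shadow of a skipping or mutually-exclusive event, not a
  shifted splice site. Without this exclusion every skipping event would
  also emit spurious AA/AD calls on the sibling isoform, and exact recovery
  of planted events would be impossible.
* **ME** — two non-overlapping internal exon runs (one per isoform) whose
  flanking introns' outer boundaries match, where every isoform of the gene
  carries exactly one of the two runs; consecutive pairs merge into one
  event (`merged_count` = run length on the evaluated isoform).

**Terminal rule.** Events whose *defining exon on the evaluated isoform* is
that isoform's first or last exon are omitted: the retaining exon for IR,
the acceptor-side exon for AA, the donor-side exon for AD, the exon runs
for ME (ES skipped exons must already be internal to the contributor).
Variation at transcript termini mostly reflects ragged assembly ends rather
than splicing. The rule is deliberately *not* applied to an ES event whose
junction intron is adjacent to a terminal exon — the defining elements of a
skip are the skipped exons, and a skip bridging from the first exon is a
genuine internal event.

Intron pairs that overlap but share neither splice site fit none of the
five categories; they are recorded in a side table of "complex" pairs and
excluded from all counts. Events are deduplicated within an isoform by
(type, span); when two siblings yield the same span with different run
lengths the larger `merged_count` is kept. AA/AD and ME are intrinsically
symmetric (each isoform carries an alternative site relative to the other),
so both isoforms of such a pair report an event; IR and ES are asymmetric
and report only on the retaining/skipping isoform.

Event quantification follows two conventions, both implemented: the
per-gene census uses the single highest-expressed transcript (ties to the
lexicographically smaller id); event expression multiplies the owning
isoform's expression by `merged_count`. The AS ratio has a `transcript`
mode (AS-isoform expression / all-isoform expression, bounded by [0, 1])
and an `event` mode (event expression / gene expression, may exceed 1 when
merged counts are > 1); samples with zero denominator are flagged NaN, not
reported as 0. Percentage shares are rounded half-up to one decimal.

## Phase clustering

Profiles are replicate-averaged per timepoint, log2(x+1)-transformed by
default (raw-scale clustering is available via a flag), and z-scored per
gene with the sample standard deviation; zero-variance genes are flagged
and excluded. Clustering is k-means (Euclidean, 25 restarts, fixed seed) at
k = 6. K-means on z-scored profiles is the simplest reproducible
partitioner for phase structure; the choice of partitioner is an
implementation decision, k = 6 is the domain convention adopted here.
Clusters are renamed by centroid peak time in the order C1 (dawn H48),
C2 (day H51–57), C3 (dusk H60), C5 (early night H63), C6 (mid night H66),
C4 (late night H69) — note C4 is the *late-night* cluster, not the fourth
largest. If two centroids peak in the same bucket the six labels are still
assigned deterministically in peak-time order (ties broken by the centroid
vector), so the naming matches the canonical scheme exactly whenever the
six peaks are distinct. Argmax ties within a centroid break to the earliest
timepoint. The cross-cultivar contingency table is computed on the shared
gene universe; the same-cluster fraction is the diagonal share, reported as
a half-up-rounded percentage.

## Cosinor fits and phase/amplitude comparison

The single-harmonic cosinor is fitted in closed form by least squares on
the design [1, cos(2πt/P), sin(2πt/P)] (P = 24 h), requiring ≥4 timepoints
spanning at least half a period. Amplitude and acrophase derive from the
two harmonic coefficients; fits with amplitude below 1e-9 × |mesor| are
flagged flat and their acrophase is treated as undefined. Cross-cultivar
comparison reports the circular acrophase difference wrapped to (−12, +12]
hours and the amplitude ratio; pairs with a flat fit are flagged. On the
8-point grid the noiseless fit is exact to numerical precision, and at
log-normal noise σ = 0.1 the median acrophase error over hundreds of genes
is ≈ 0.15 h.

## Chromosome activity

Counts are normalized in three steps: counts-per-million within each sample
(the normalization itself is an implementation choice; CPM is the simplest
depth-invariant one), replicate averaging per timepoint, per-chromosome
z-standardization across timepoints (zero-variance rows flagged).
Chromosomes and timepoints are clustered by agglomerative average-linkage
Euclidean clustering with the tree cut at k = 6 and k = 3 respectively —
chosen over k-means here for determinism without a seed. CG labels are
ordered by group mean peak time; TG labels by earliest member timepoint
(the biologically meaningful output is the partition, not the numbering).

## DEG calling and 12-h merging

No specific DE caller is canonical for three-replicate TPM tables, so the
package uses a minimal, transparent test: Welch's unequal-variance t-test
on log2(TPM+1), BH adjustment across genes within a timepoint, and
`is_deg = (fdr ≤ α) ∧ (|log2FC| ≥ lfc_min)` with α = 0.05 and lfc_min = 1
by default. Genes with zero variance in both groups get p = 1 when the
means are equal. With 3 vs 3 replicates the Welch test is slightly
conservative (null p < 0.05 fraction ≈ 0.036–0.04 rather than 0.05), which
errs on the safe side for discovery. The 12-h merged-sample strategy pairs
replicate i at t with replicate i at t+12 and averages them (mean, not sum,
preserving the TPM scale); on the default grid exactly four merged pairs
exist (48/60, 51/63, 54/66, 57/69). Overlap analysis reports pairwise
intersections for any number of sets and the full Venn partition for up to
four.

## Polymorphism profile

Each gene defines nine strand-aware bins tiling [TSS−10 kb, TES+10 kb]: the
flank labels denote *annuli* (U2K = 2–1 kb upstream, etc.), not cumulative
windows — annuli make the nine bins a partition, so each variant in a
gene's window increments exactly one bin of that gene (a `--cumulative`
reading would double-count; the annular convention is the package default
and the generator's convention). A variant inside several genes' windows
counts once per gene. Counts are normalized per kilobase (BODY length
varies per gene) before group means and the discordant/concordant ratio are
taken; bins with zero control mean are flagged undefined.

## Synthetic data: what it emulates, what it does not

The generators plant known structure under the study design: 6-exon gene
scaffolds (200 b exons, 300 b introns, 40 kb spacing over 20 chromosomes,
random strand) with one alternative isoform per AS gene embodying exactly
one event type — including skip runs of length 2 (the consecutive-ES merge
case) and terminal-retention "trap" genes whose event must *not* be
reported; cosine-rhythmic expression in six phase groups (default
acrophases 48/54/60/63/66/69 HPE, baseline 20, amplitude 10, multiplicative
log-normal noise σ = 0.2) with optional per-cultivar phase shifts or
amplitude rescalings; Poisson variants at 2/kb enriched 3-fold around
discordant genes except in U2K/U1K; and Poisson chromosome counts
(baseline 5×10⁴ per sample, relative amplitude 0.4, log-normal depth
factors σ = 0.2) in six phase groups, plus a "blocked" variant whose
timepoint profiles are constant within morning/afternoon/night blocks.
Gene-level matrices are the exact column sums of their transcript rows, and
all generators are deterministic under a fixed seed.

Noise models were chosen as the fewest-parameter forms matching RNA-seq
behaviour: multiplicative log-normal for abundances, Poisson for counts.
The generator does **not** emulate read-level artifacts (mappability, GC
bias), transcript-assembly errors, gene–gene correlation, non-sinusoidal
waveforms, or linkage structure between variants. Passing recovery tests
therefore demonstrates the correctness of the algorithms under the stated
stochastic model, not robustness to the full messiness of real libraries.

## Problem sizes and numerical choices

Recovery benchmarks run at 200–1000 genes, 20 chromosomes, 50 null DEG
runs of 2,000 genes — sizes at which every planted effect is comfortably
identified and the whole validation suite completes in seconds on one core.
Scaling constants (z-score tolerance 1e-9, flat-fit threshold 1e-9 × mesor,
half-up rounding of printed percentages) are fixed in code. Determinism:
k-means uses an explicit seed and 25 restarts; hierarchical clustering and
the cosinor closed form need none; all generators take a seed.

## Known limitations

* The event classifier assumes each isoform's exons are disjoint and
  correctly stranded; trans-splicing and intra-exonic micro-variation
  (pairs sharing neither splice site) land in the complex side table.
* ME detection uses the strict gene-wide "every isoform carries exactly one
  of the two runs" condition; permissive MXE definitions would call more.
* The DEG module is a per-timepoint two-group test; it is deliberately not
  a time-course model, since its purpose is to show the instability of
  snapshot comparisons.
* Cosinor fits assume a known 24-h period; period estimation is out of
  scope.
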