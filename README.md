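# chronotome

Circadian dissection of bulk RNA-seq time series, built for designs like a
two-cultivar soybean experiment: plants entrained in 12 h light : 12 h dark,
released into continuous light, and sampled every 3 h from 48 to 69 hours
post entrainment (HPE) with three biological replicates. Because virtually
every gene oscillates under such a design, snapshot-style analyses
(differential expression at one timepoint) are unstable; this package
implements the time-aware analyses that are robust to that oscillation, plus
a synthetic-data generator with known ground truth so every stage is
testable without the original sequencing data.

## What it computes

**Alternative-splicing events.** All isoforms of a gene are merged into one
composite gene model (exon union + pooled intron catalogue) and each isoform
is classified against it into the five canonical local events: intron
retention (IR), alternative 3′ acceptor (AA), alternative 5′ donor (AD),
exon skipping (ES) and mutually exclusive exons (ME). Runs of consecutively
skipped (or mutually exclusive) exons merge into one event with a
`merged_count`; events whose defining exon is the isoform's first or last
exon are omitted (assembled transcript termini are unreliable). Event
expression is the owning isoform's expression × `merged_count`, and the AS
ratio per sample is either AS-transcript expression over total transcript
expression (`transcript` mode, in [0, 1]) or event expression over gene
expression (`event` mode).

**Phase clustering and cosinor fits.** Replicate-averaged, log2-scaled,
z-scored profiles are k-means partitioned into six phase clusters C1–C6
named by centroid peak (C1 dawn H48, C2 day H51–57, C3 dusk H60, C5/C6/C4
early/mid/late night). Each gene's rhythm is summarized by the cosinor model

    x(t) = M + A·cos(2π(t − φ)/24)

fitted in closed form via x(t) = M + a·cos(2πt/24) + b·sin(2πt/24), with
amplitude A = √(a²+b²) and acrophase φ = (24/2π)·atan2(b, a) mod 24. Between
cultivars, Δφ (circular, in (−12, +12] h) and the amplitude ratio separate
*phase modulation* from *amplitude modulation* of a rhythm.

**Chromosome activation.** Per-chromosome mapped-read counts are normalized
(counts-per-million per sample, replicate averaging, per-chromosome
z-scores) and co-clustered hierarchically: chromosomes into six groups
(CG1..CG6) and timepoints into three (TG1..TG3, e.g. morning {48,51} /
afternoon {54,57,60} / night {63,66,69}).

**Per-timepoint DEGs and 12-h merging.** Welch's t-test on log2(TPM+1) with
Benjamini–Hochberg adjustment per timepoint; a simulated 12-h-spaced design
merges replicate-paired samples 12 h apart (48/60, 51/63, 54/66, 57/69) by
arithmetic mean; overlap tables and Venn partitions quantify how strongly
DEG calls depend on sampling time.

**Flanking polymorphism.** Variants are assigned to nine strand-aware bins
per gene (U10K/U5K/U2K/U1K upstream annuli, BODY, D1K/D2K/D5K/D10K
downstream), normalized per kilobase, and compared between genes whose
phase cluster is concordant vs discordant across cultivars.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (bulky tables go to `scratch/sim/`, summaries to `results/`):

```
python analysis/01_simulate.py --seed 1
python analysis/02_splice_events.py
python analysis/03_phase_clusters.py --seed 1
python analysis/04_chromosome_activity.py
python analysis/05_deg_timepoints.py
python analysis/06_polymorphism.py
```

With seed 1 this prints, among other lines:

```
simulated 300 genes (180 planted events, 60 phase-discordant in ZH24), 18591 variants, 20 chromosomes
120/300 genes with AS; events per type: {'IR': 45, 'AD': 42, 'ES': 15, 'AA': 72, 'ME': 6}
same-cluster fraction HX3 vs ZH24: 80.0 %
median |delta acrophase| (h): planted-shifted 11.57, others 0.43
chromosome-group ARI vs planted truth: 1.000
timepoint partition (blocked table): [[48, 51], [54, 57, 60], [63, 66, 69]]
DEGs per timepoint: {'H48': 10, 'H51': 8, 'H54': 2, 'H57': 7, 'H60': 8, 'H63': 4, 'H66': 0, 'H69': 0}
genes DE at ALL timepoints: 0
```

Reading these: 60 of 300 genes were planted with a 12-h phase shift in
cultivar ZH24, and the cross-cultivar clustering finds exactly the planted
80 % concordance; the cosinor comparison isolates the shifted genes (median
|Δφ| ≈ 12 h vs 0.4 h for unshifted ones); chromosome phase groups are
recovered perfectly; and although individual timepoints yield up to ten
DEGs, not a single gene is differentially expressed at every timepoint —
the oscillation, not the genotype, dominates snapshot comparisons. The
polymorphism step then shows the planted ~3-fold variant enrichment around
cluster-discordant genes in every bin except the 2–1 kb upstream shells
(ratios ≈ 1 there).

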