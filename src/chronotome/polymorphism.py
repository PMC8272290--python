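"""Variant density around genes: body and flanking-shell counts and ratios.

Each gene defines nine strand-aware region bins tiling [TSS-10kb, TES+10kb]:
four upstream annuli (U10K = 10-5 kb, U5K = 5-2 kb, U2K = 2-1 kb, U1K =
1-0 kb before the TSS), the gene BODY, and four mirrored downstream annuli
(D1K..D10K). "Upstream" is 5' of the TSS on the gene's own strand, so for a
minus-strand gene the U bins lie to the genomic right. Counts are normalized
per kilobase so the variable-length BODY is comparable to the fixed shells,
then compared between two gene groups (typically genes whose phase cluster
is concordant vs discordant between cultivars) as the discordant/concordant
ratio per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import TranscriptModel, ValidationError

#: Bin labels in upstream-to-downstream (transcription) order.
BIN_LABELS: tuple[str, ...] = (
    "U10K", "U5K", "U2K", "U1K", "BODY", "D1K", "D2K", "D5K", "D10K",
)

#: Flank shell edges in bases from the gene boundary (annular windows).
_SHELL_EDGES: tuple[tuple[str, int, int], ...] = (
    ("1K", 0, 1000),
    ("2K", 1000, 2000),
    ("5K", 2000, 5000),
    ("10K", 5000, 10000),
)


@dataclass(frozen=True)
class GeneSpan:
    """Genomic footprint of one gene (composite span over isoforms)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def gene_span(isoforms: Sequence[TranscriptModel]) -> GeneSpan:
    if not isoforms:
        raise ValidationError("need >= 1 isoform")
    return GeneSpan(
        gene_id=isoforms[0].gene_id,
        chrom=isoforms[0].chrom,
        start=min(t.start for t in isoforms),
        end=max(t.end for t in isoforms),
        strand=isoforms[0].strand,
    )


def region_bins(gene: GeneSpan) -> dict[str, tuple[int, int]]:
    """The nine strand-aware bins of one gene as half-open intervals.

    The bins tile [start-10000, end+10000) without overlap; intervals may
    extend below zero for genes near a chromosome start (callers counting
    variants are unaffected since positions are non-negative).
    """
    bins: dict[str, tuple[int, int]] = {"BODY": (gene.start, gene.end)}
    for name, lo, hi in _SHELL_EDGES:
        if gene.strand == "+":
            bins[f"U{name}"] = (gene.start - hi, gene.start - lo)
            bins[f"D{name}"] = (gene.end + lo, gene.end + hi)
        else:
            bins[f"U{name}"] = (gene.end + lo, gene.end + hi)
            bins[f"D{name}"] = (gene.start - hi, gene.start - lo)
    return bins


def bin_widths_kb(gene: GeneSpan) -> dict[str, float]:
    return {
        label: (hi - lo) / 1000.0 for label, (lo, hi) in region_bins(gene).items()
    }


def assign_variant_bins(
    variants: Sequence[tuple[str, int]],
    genes: Sequence[GeneSpan],
) -> tuple[pd.DataFrame, int]:
    """Count variants per gene per region bin.

    A variant inside a gene's +/-10 kb window increments exactly one bin of
    that gene; a variant inside the windows of several genes counts once per
    gene. Returns the genes x bins count table and the number of variants on
    chromosomes absent from the annotation (skipped).
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for label, (lo, hi) in region_bins(gene).items():
            if hi > max(lo, 0):
                tree.addi(max(lo, 0), hi, (gene.gene_id, label))

    counts = pd.DataFrame(
        0, index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=list(BIN_LABELS),
    )
    n_skipped = 0
    for chrom, pos in variants:
        tree = trees.get(chrom)
        if tree is None:
            n_skipped += 1
            continue
        for hit in tree.at(pos):
            gene_id, label = hit.data
            counts.loc[gene_id, label] += 1
    return counts, n_skipped


def bin_count_ratio(
    counts: pd.DataFrame,
    gene_groups: Mapping[str, str],
    widths_kb: Mapping[str, Mapping[str, float]] | None = None,
    control: str = "concordant",
    treatment: str = "discordant",
) -> pd.DataFrame:
    """Per-bin polymorphism ratio of the treatment group over the control.

    Counts are converted to per-kilobase rates per gene (``widths_kb`` maps
    gene -> bin -> width; flank widths are used when omitted and BODY then
    needs explicit widths), averaged within each group, and the ratio
    treatment/control is reported per bin. The control ratio is 1 by
    construction; bins with zero control mean are flagged undefined (NaN).
    """
    for group in (control, treatment):
        if not any(v == group for v in gene_groups.values()):
            raise ValidationError(f"gene group {group!r} is empty")
    per_kb = counts.astype(float).copy()
    if widths_kb is not None:
        for gene_id in per_kb.index:
            for label in BIN_LABELS:
                per_kb.loc[gene_id, label] /= widths_kb[gene_id][label]
    else:
        raise ValidationError("widths_kb required for per-kb normalization")

    groups = pd.Series({g: gene_groups[g] for g in per_kb.index})
    mean_control = per_kb[groups == control].mean(axis=0)
    mean_treatment = per_kb[groups == treatment].mean(axis=0)
    ratio = mean_treatment / mean_control.where(mean_control > 0)
    return pd.DataFrame(
        {
            "mean_control_per_kb": mean_control,
            "mean_treatment_per_kb": mean_treatment,
            "ratio": ratio,
            "undefined": mean_control <= 0,
        }
    )
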