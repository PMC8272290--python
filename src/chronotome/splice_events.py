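"""Alternative-splicing event calling against a composite gene model.

All isoforms of a gene are merged into one composite model (exon union plus
the pooled intron catalogue). Each isoform is then compared against that
composite and its sibling isoforms, and local differences are classified
into the five canonical event types:

* IR - intron retention: an internal exon of the isoform fully contains an
  intron contributed by a sibling isoform.
* ES - exon skipping: an intron of the isoform spans one or more consecutive
  internal exons of a sibling isoform whose flanking exon boundaries
  coincide with the intron's ends; a run of consecutively skipped exons
  counts as ONE event whose ``merged_count`` is the run length.
* AA / AD - alternative 3' acceptor / 5' donor: two introns share one splice
  site (on the transcription strand) and differ at the other, with no whole
  exon inside the difference region (such pairs are skipping/mutually
  exclusive bubbles, not shifted sites).
* ME - mutually exclusive exons: two non-overlapping internal exon runs with
  matching outer flank boundaries, where every isoform of the gene carries
  exactly one of the two runs; consecutive pairs merge into one event.

Events whose defining exon on the evaluated isoform is that isoform's first
or last exon are omitted, mirroring the exclusion of variation at transcript
beginnings/ends (assembled transcript termini are unreliable). Intron pairs
that overlap but share neither splice site fit none of the five types and
are set aside as "complex" pairs, excluded from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    TimeSeriesMatrix,
    TranscriptModel,
    ValidationError,
)

EVENT_TYPES: tuple[str, ...] = ("IR", "AA", "AD", "ES", "ME")


@dataclass(frozen=True, order=True)
class ASEvent:
    """One classified alternative-splicing event.

    ``merged_count`` is the number of primitive occurrences merged into the
    event (run length for ES/ME; always 1 for IR/AA/AD).
    """

    gene_id: str
    isoform_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    merged_count: int = 1

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.merged_count < 1:
            raise ValidationError("merged_count must be >= 1")
        if self.event_type in ("IR", "AA", "AD") and self.merged_count != 1:
            raise ValidationError(f"{self.event_type} events cannot merge occurrences")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ComplexPair:
    """Overlapping intron pair sharing neither splice site (side table)."""

    gene_id: str
    isoform_id: str
    intron: tuple[int, int]
    other_intron: tuple[int, int]


@dataclass(frozen=True)
class CompositeGeneModel:
    """Per-gene exon union plus pooled intron catalogue of all isoforms."""

    gene_id: str
    chrom: str
    strand: str
    merged_exons: tuple[tuple[int, int], ...]
    intron_catalogue: Mapping[tuple[int, int], frozenset[str]]
    isoforms: tuple[TranscriptModel, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.merged_exons[0][0], self.merged_exons[-1][1])


def build_composite_model(isoforms: Sequence[TranscriptModel]) -> CompositeGeneModel:
    """Merge all isoforms of one gene into a composite gene model."""
    if not isoforms:
        raise ValidationError("need >= 1 isoform")
    gene_ids = {t.gene_id for t in isoforms}
    chroms = {t.chrom for t in isoforms}
    strands = {t.strand for t in isoforms}
    if len(gene_ids) > 1:
        raise ValidationError(f"isoforms from multiple genes: {sorted(gene_ids)}")
    if len(chroms) > 1 or len(strands) > 1:
        raise ValidationError("isoforms on mixed chromosomes/strands")

    # sweep-line union of exons
    intervals = sorted((e.start, e.end) for t in isoforms for e in t.exons)
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))

    catalogue: dict[tuple[int, int], set[str]] = {}
    for t in isoforms:
        for intron in t.introns:
            catalogue.setdefault(intron, set()).add(t.transcript_id)

    return CompositeGeneModel(
        gene_id=isoforms[0].gene_id,
        chrom=isoforms[0].chrom,
        strand=isoforms[0].strand,
        merged_exons=tuple(merged),
        intron_catalogue={k: frozenset(v) for k, v in catalogue.items()},
        isoforms=tuple(sorted(isoforms, key=lambda t: t.transcript_id)),
    )


def _donor(intron: tuple[int, int], strand: str) -> int:
    """5' splice site on the transcription strand."""
    return intron[0] if strand == "+" else intron[1]


def _acceptor(intron: tuple[int, int], strand: str) -> int:
    return intron[1] if strand == "+" else intron[0]


def call_events(
    composite: CompositeGeneModel,
    isoform: TranscriptModel,
    complex_out: list[ComplexPair] | None = None,
) -> list[ASEvent]:
    """Classify the AS events exhibited by one isoform against the composite.

    Events are deduplicated within the isoform by (type, span); where two
    sibling isoforms produce the same span with different run lengths the
    larger ``merged_count`` is kept.
    """
    if isoform.gene_id != composite.gene_id:
        raise ValidationError(
            f"isoform {isoform.transcript_id} belongs to gene {isoform.gene_id}, "
            f"not {composite.gene_id}"
        )
    exons = isoform.exons
    n = len(exons)
    strand = isoform.strand
    introns = isoform.introns
    tid = isoform.transcript_id
    siblings = [t for t in composite.isoforms if t.transcript_id != tid]

    # internal exons of every isoform, for the AA/AD difference-region test
    internal_all = {
        (e.start, e.end) for t in composite.isoforms for e in t.exons[1:-1]
    }

    def region_holds_exon(lo: int, hi: int) -> bool:
        return any(lo <= xs and xe <= hi for xs, xe in internal_all)

    found: dict[tuple[str, tuple[int, int]], int] = {}

    def add(etype: str, span: tuple[int, int], count: int) -> None:
        key = (etype, span)
        found[key] = max(found.get(key, 0), count)

    # --- IR: internal exon retains a catalogued intron of a sibling -------
    for ex in exons[1:-1]:
        for (istart, iend), contribs in composite.intron_catalogue.items():
            if ex.start < istart and iend < ex.end and (contribs - {tid}):
                add("IR", (istart, iend), 1)

    # --- per-intron comparisons ------------------------------------------
    for j, (ts, te) in enumerate(introns):
        # ES: sibling run flanked by exon boundaries matching this intron
        for sib in siblings:
            ends = {e.end: i for i, e in enumerate(sib.exons)}
            starts = {e.start: i for i, e in enumerate(sib.exons)}
            i = ends.get(ts)
            k = starts.get(te)
            if i is not None and k is not None and k > i + 1:
                run = sib.exons[i + 1 : k]
                add("ES", (run[0].start, run[-1].end), len(run))

        # AA/AD/complex against the pooled intron catalogue
        t_d, t_a = _donor((ts, te), strand), _acceptor((ts, te), strand)
        for (ss, se), contribs in composite.intron_catalogue.items():
            if not (contribs - {tid}) or (ss, se) == (ts, te):
                continue
            s_d, s_a = _donor((ss, se), strand), _acceptor((ss, se), strand)
            if t_d == s_d and t_a != s_a:
                lo, hi = sorted((t_a, s_a))
                if region_holds_exon(lo, hi):
                    continue
                acc_idx = j + 1 if strand == "+" else j
                if acc_idx in (0, n - 1):
                    continue
                add("AA", (ts, te), 1)
            elif t_a == s_a and t_d != s_d:
                lo, hi = sorted((t_d, s_d))
                if region_holds_exon(lo, hi):
                    continue
                don_idx = j if strand == "+" else j + 1
                if don_idx in (0, n - 1):
                    continue
                add("AD", (ts, te), 1)
            elif ts < se and ss < te:  # overlap, neither site shared
                if complex_out is not None:
                    complex_out.append(
                        ComplexPair(composite.gene_id, tid, (ts, te), (ss, se))
                    )

    # --- ME: mutually exclusive internal exon runs ------------------------
    for sib in siblings:
        sib_end_idx = {e.end: i for i, e in enumerate(sib.exons)}
        sib_start_idx = {e.start: i for i, e in enumerate(sib.exons)}
        for a in range(n - 1):
            p = sib_end_idx.get(exons[a].end)
            if p is None:
                continue
            for b in range(a + 2, n):
                q = sib_start_idx.get(exons[b].start)
                if q is None or q <= p + 1:
                    continue
                own_run = exons[a + 1 : b]
                sib_run = sib.exons[p + 1 : q]
                if any(
                    x.start < y.end and y.start < x.end
                    for x in own_run
                    for y in sib_run
                ):
                    continue
                own_set = {(e.start, e.end) for e in own_run}
                sib_set = {(e.start, e.end) for e in sib_run}
                exclusive = True
                for t in composite.isoforms:
                    tset = {(e.start, e.end) for e in t.exons}
                    has_own = own_set <= tset and not (sib_set & tset)
                    has_sib = sib_set <= tset and not (own_set & tset)
                    if not (has_own or has_sib):
                        exclusive = False
                        break
                if not exclusive:
                    continue
                span = (
                    min(own_run[0].start, sib_run[0].start),
                    max(own_run[-1].end, sib_run[-1].end),
                )
                add("ME", span, len(own_run))

    return sorted(
        ASEvent(
            gene_id=composite.gene_id,
            isoform_id=tid,
            event_type=etype,
            chrom=composite.chrom,
            start=span[0],
            end=span[1],
            strand=strand,
            merged_count=count,
        )
        for (etype, span), count in found.items()
    )


@dataclass
class GeneClassification:
    """Event table of one gene plus its AS status."""

    gene_id: str
    events: list[ASEvent]
    complex_pairs: list[ComplexPair] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "AS" if self.events else "no_AS"


def classify_gene(isoforms: Sequence[TranscriptModel]) -> GeneClassification:
    """Build the composite internally and call events for every isoform."""
    composite = build_composite_model(isoforms)
    events: list[ASEvent] = []
    complex_pairs: list[ComplexPair] = []
    for iso in composite.isoforms:
        events.extend(call_events(composite, iso, complex_out=complex_pairs))
    return GeneClassification(composite.gene_id, events, complex_pairs)


def classify_annotation(
    annotation: Mapping[str, Sequence[TranscriptModel]],
) -> dict[str, GeneClassification]:
    return {g: classify_gene(isoforms) for g, isoforms in annotation.items()}


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "transcript_id": e.isoform_id,
                "type": e.event_type,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "merged_count": e.merged_count,
            }
            for e in events
        ],
        columns=[
            "gene_id",
            "transcript_id",
            "type",
            "chrom",
            "start",
            "end",
            "strand",
            "merged_count",
        ],
    )


def _total_expression(matrix: TimeSeriesMatrix, transcript_id: str) -> float:
    if transcript_id not in matrix.data.index:
        raise KeyError(f"no expression for transcript {transcript_id!r}")
    return float(matrix.data.loc[transcript_id].sum())


def representative_event_counts(
    isoforms: Sequence[TranscriptModel],
    transcript_expression: TimeSeriesMatrix,
) -> dict[str, int]:
    """Event-type counts of the gene's single highest-expressed isoform.

    The representative transcript is the one with maximal total expression
    over all samples; ties break to the lexicographically smaller id.
    """
    classification = classify_gene(isoforms)
    ranked = sorted(
        isoforms,
        key=lambda t: (-_total_expression(transcript_expression, t.transcript_id),
                       t.transcript_id),
    )
    rep = ranked[0].transcript_id
    counts: dict[str, int] = {}
    for ev in classification.events:
        if ev.isoform_id == rep:
            counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
    return counts


def event_expression_series(
    events: Sequence[ASEvent],
    transcript_expression: TimeSeriesMatrix,
) -> pd.DataFrame:
    """Per-sample total event expression per type.

    One event contributes its owning isoform's expression multiplied by its
    ``merged_count`` in every sample.
    """
    cols = transcript_expression.data.columns
    out = pd.DataFrame(0.0, index=list(EVENT_TYPES), columns=cols)
    for ev in events:
        if ev.isoform_id not in transcript_expression.data.index:
            raise KeyError(f"no expression for transcript {ev.isoform_id!r}")
        out.loc[ev.event_type] += (
            transcript_expression.data.loc[ev.isoform_id] * ev.merged_count
        )
    return out


@dataclass
class ASRatioResult:
    """Per-gene and genome-wide AS ratios per sample (NaN where undefined)."""

    mode: str
    per_gene: pd.DataFrame
    genome_wide: pd.Series


def as_ratio_series(
    annotation: Mapping[str, Sequence[TranscriptModel]],
    transcript_expression: TimeSeriesMatrix,
    mode: str = "transcript",
) -> ASRatioResult:
    """AS ratio per gene and genome-wide, per sample.

    ``transcript`` mode: expression of event-bearing isoforms over total
    isoform expression (in [0, 1] wherever defined). ``event`` mode: total
    event expression (merged_count-weighted) over total gene expression (may
    exceed 1). Samples with zero denominator yield NaN rather than 0.
    """
    if mode not in ("transcript", "event"):
        raise ValueError(f"mode must be 'transcript' or 'event', got {mode!r}")
    expr = transcript_expression.data
    cols = expr.columns
    num_total = pd.Series(0.0, index=cols)
    den_total = pd.Series(0.0, index=cols)
    rows = {}
    for gene_id in sorted(annotation):
        isoforms = annotation[gene_id]
        classification = classify_gene(isoforms)
        tids = [t.transcript_id for t in isoforms]
        gene_total = expr.loc[tids].sum(axis=0)
        if mode == "transcript":
            as_tids = sorted({e.isoform_id for e in classification.events})
            num = (
                expr.loc[as_tids].sum(axis=0)
                if as_tids
                else pd.Series(0.0, index=cols)
            )
        else:
            num = pd.Series(0.0, index=cols)
            for ev in classification.events:
                num += expr.loc[ev.isoform_id] * ev.merged_count
        rows[gene_id] = (num / gene_total.where(gene_total > 0)).astype(float)
        num_total += num
        den_total += gene_total
    per_gene = pd.DataFrame(rows).T
    per_gene.columns = cols
    genome_wide = num_total / den_total.where(den_total > 0)
    return ASRatioResult(mode, per_gene, genome_wide)


def event_type_shares(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage share per event type, rounded half-up to one decimal."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total event count must be positive")
    shares = {}
    for etype, c in counts.items():
        pct = Decimal(c) * 100 / Decimal(total)
        shares[etype] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return shares
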