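"""Readers/writers and shared domain types.

All genomic coordinates are handled internally as 0-based, half-open
intervals; the external text formats (GTF, VCF, variant tables) follow their
standard 1-based, inclusive conventions and are converted on the way in/out.

Samples of the time-series design are keyed by cultivar, timepoint in hours
post entrainment (HPE) and replicate, formatted ``CULTIVAR_H<hpe>_R<rep>``
in table headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sampling grid of the study design: 48-69 HPE every 3 h.
DEFAULT_TIMEPOINTS: tuple[int, ...] = (48, 51, 54, 57, 60, 63, 66, 69)

#: Circadian period in hours.
PERIOD_H: float = 24.0


class ParseError(ValueError):
    """A text record could not be parsed (message names the line)."""


class ValidationError(ValueError):
    """Parsed data violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based, half-open stranded interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered, disjoint exon intervals on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on multiple chromosomes")
        if len(strands) > 1:
            raise ValidationError(f"{self.transcript_id}: mixed strands within transcript")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.transcript_id}: exons must be ascending with gaps >= 1 base"
                )

    @classmethod
    def from_coords(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
    ) -> "TranscriptModel":
        ivs = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons)
        )
        return cls(transcript_id, gene_id, ivs)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons as (start, end) pairs."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )


_SAMPLE_RE = re.compile(r"^(?P<cultivar>.+)_H(?P<tp>\d+)_R(?P<rep>\d+)$")


@dataclass(frozen=True, order=True)
class SampleKey:
    """cultivar x timepoint (HPE) x replicate identifier of one sample."""

    cultivar: str
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")

    def __str__(self) -> str:
        return f"{self.cultivar}_H{self.timepoint}_R{self.replicate}"

    @classmethod
    def parse(
        cls, token: str, timepoint_grid: Sequence[int] = DEFAULT_TIMEPOINTS
    ) -> "SampleKey":
        m = _SAMPLE_RE.match(token)
        if m is None:
            raise ParseError(f"unparseable sample key {token!r}")
        tp = int(m.group("tp"))
        if timepoint_grid is not None and tp not in timepoint_grid:
            raise ValidationError(
                f"timepoint {tp} of sample {token!r} not on grid {tuple(timepoint_grid)}"
            )
        return cls(m.group("cultivar"), tp, int(m.group("rep")))


class TimeSeriesMatrix:
    """Features x samples non-negative matrix with sample-key metadata.

    The columns are a pandas MultiIndex (cultivar, timepoint, replicate) so
    that downstream replicate averaging and cultivar selection are plain
    groupby operations.
    """

    COLUMN_NAMES = ("cultivar", "timepoint", "replicate")

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("matrix contains negative values")
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValidationError("columns must be a (cultivar, timepoint, replicate) MultiIndex")
        data = data.copy()
        data.columns = data.columns.set_names(self.COLUMN_NAMES)
        self.data = data

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Sequence[str],
        samples: Sequence[SampleKey],
        values: np.ndarray,
    ) -> "TimeSeriesMatrix":
        cols = pd.MultiIndex.from_tuples(
            [(s.cultivar, s.timepoint, s.replicate) for s in samples],
            names=cls.COLUMN_NAMES,
        )
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=pd.Index(feature_ids), columns=cols))

    # -- metadata ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(c, t, r) for c, t, r in self.data.columns]

    @property
    def cultivars(self) -> list[str]:
        return sorted(self.data.columns.get_level_values("cultivar").unique())

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.data.columns.get_level_values("timepoint").unique())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    # -- views ------------------------------------------------------------
    def select_cultivar(self, cultivar: str) -> "TimeSeriesMatrix":
        if cultivar not in self.cultivars:
            raise KeyError(f"cultivar {cultivar!r} not present")
        sub = self.data.loc[:, self.data.columns.get_level_values("cultivar") == cultivar]
        return TimeSeriesMatrix(sub)

    def replicate_mean(self, cultivar: str | None = None) -> pd.DataFrame:
        """Average replicates per timepoint; returns features x timepoints."""
        tsm = self if cultivar is None else self.select_cultivar(cultivar)
        if len(tsm.cultivars) != 1:
            raise ValidationError("replicate_mean needs a single cultivar; pass cultivar=")
        out = tsm.data.T.groupby(level="timepoint").mean().T
        return out.reindex(columns=sorted(out.columns))

    def replicate_vectors(self, cultivar: str, timepoint: int) -> pd.DataFrame:
        """Features x replicates table for one cultivar/timepoint cell."""
        mask = (
            (self.data.columns.get_level_values("cultivar") == cultivar)
            & (self.data.columns.get_level_values("timepoint") == timepoint)
        )
        sub = self.data.loc[:, mask]
        sub.columns = sub.columns.get_level_values("replicate")
        return sub


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> dict[str, list[TranscriptModel]]:
    """Parse exon features of a GTF file into per-gene transcript models.

    Only ``exon`` features are consumed; coordinates are converted from the
    1-based inclusive GTF convention to internal 0-based half-open. Exons are
    grouped per transcript (sorted by start) and transcripts per gene.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    order: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"line {lineno}: exon end {end1} < start {start1}")
            attr_map = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr_map or "transcript_id" not in attr_map:
                raise ParseError(f"line {lineno}: exon lacks gene_id/transcript_id attributes")
            key = (attr_map["gene_id"], attr_map["transcript_id"])
            if key not in exons:
                exons[key] = []
                order.append(key)
            try:
                exons[key].append(GenomicInterval(chrom, start1 - 1, end1, strand))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc

    annotation: dict[str, list[TranscriptModel]] = {}
    for gene_id, transcript_id in order:
        ivs = tuple(sorted(exons[(gene_id, transcript_id)], key=lambda e: e.start))
        model = TranscriptModel(transcript_id, gene_id, ivs)
        annotation.setdefault(gene_id, []).append(model)
    for gene_id in annotation:
        annotation[gene_id].sort(key=lambda t: t.transcript_id)
    return annotation


def write_gtf(annotation: Mapping[str, Sequence[TranscriptModel]], path) -> None:
    """Emit 1-based inclusive GTF exon lines, deterministically ordered."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id in sorted(annotation):
            for tx in sorted(annotation[gene_id], key=lambda t: t.transcript_id):
                for exon in sorted(tx.exons, key=lambda e: e.start):
                    attrs = f'gene_id "{gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                ".",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Expression / count matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path,
    kind: str = "expression",
    timepoint_grid: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> TimeSeriesMatrix:
    """Read a tab-separated features x samples table.

    The header row carries sample keys ``CULTIVAR_H<hpe>_R<rep>``; values are
    coerced to non-negative reals (``kind`` is documentation of intent; both
    expression and count tables share the container).
    """
    if kind not in ("expression", "counts"):
        raise ValueError(f"kind must be 'expression' or 'counts', got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate feature id {dup!r}")
    keys = [SampleKey.parse(str(c), timepoint_grid) for c in df.columns]
    return TimeSeriesMatrix.from_arrays(list(df.index), keys, df.to_numpy(dtype=float))


def write_matrix(matrix: TimeSeriesMatrix, path) -> None:
    out = matrix.data.copy()
    out.columns = [str(k) for k in matrix.samples]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variants(path) -> list[tuple[str, int]]:
    """Read (chrom, position) pairs from a 2+ column TSV or a VCF.

    Header/comment lines starting with ``#`` are skipped; positions are
    1-based in the file and converted to internal 0-based.
    """
    variants: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected >=2 tab-separated columns")
            try:
                pos1 = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer position {fields[1]!r}") from exc
            variants.append((fields[0], pos1 - 1))
    return variants


def write_variants(variants: Iterable[tuple[str, int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, pos0 in variants:
            fh.write(f"{chrom}\t{pos0 + 1}\n")
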