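"""Synthetic ground-truth generators for the whole pipeline.

The generators emulate the study design the pipeline targets: two cultivars
sampled at 8 timepoints (48-69 hours post entrainment, every 3 h) with 3
replicates; genes oscillating with a 24-h period in six phase groups;
isoforms carrying planted alternative-splicing events of all five types;
20 chromosomes with group-level phase effects; and variants enriched around
phase-discordant genes everywhere except the 2-1 kb upstream shells.

Noise models: multiplicative log-normal noise for expression (TPM-like
abundances), Poisson sampling for read counts and variant counts. Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    DEFAULT_TIMEPOINTS,
    PERIOD_H,
    TimeSeriesMatrix,
    SampleKey,
    TranscriptModel,
    ValidationError,
)
from .polymorphism import BIN_LABELS, GeneSpan, gene_span, region_bins

EVENT_TYPES = ("IR", "AA", "AD", "ES", "ME")

#: Default phase-group acrophases (HPE): dawn, day, dusk and the three night
#: groups, anchored at H48/H54/H60/H63/H66/H69.
DEFAULT_GROUP_ACROPHASES: tuple[float, ...] = (48, 54, 60, 63, 66, 69)

#: Default per-gene event-type fractions; the remainder of genes carry a
#: single isoform. Roughly mirrors observed type prevalence (IR most common,
#: ME rare) with ~40% of genes alternatively spliced.
DEFAULT_EVENT_MIX: dict[str, float] = {
    "IR": 0.15,
    "AA": 0.12,
    "AD": 0.07,
    "ES": 0.05,
    "ME": 0.01,
}


@dataclass(frozen=True)
class RhythmSpec:
    """Cosine rhythm parameters of one phase group.

    ``baseline`` is the mesor-like mean abundance, ``amplitude`` the cosine
    half-range (same units, must not exceed the baseline so expectations
    stay non-negative), ``acrophase`` the peak time in HPE modulo the 24-h
    period, and ``noise_sd`` the s.d. of multiplicative log-scale noise.
    """

    baseline: float
    amplitude: float
    acrophase: float
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValidationError("baseline must be > 0")
        if not 0 <= self.amplitude <= self.baseline:
            raise ValidationError("amplitude must be in [0, baseline]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def mean_at(self, t: float, phase_shift: float = 0.0,
                amplitude_scale: float = 1.0) -> float:
        amp = self.amplitude * amplitude_scale
        if amp > self.baseline:
            raise ValidationError("scaled amplitude exceeds baseline")
        return self.baseline + amp * math.cos(
            2 * math.pi * (t - (self.acrophase + phase_shift)) / PERIOD_H
        )


def default_phase_groups(
    baseline: float = 20.0,
    amplitude: float = 10.0,
    noise_sd: float = 0.2,
    acrophases: Sequence[float] = DEFAULT_GROUP_ACROPHASES,
) -> list[RhythmSpec]:
    return [RhythmSpec(baseline, amplitude, a, noise_sd) for a in acrophases]


@dataclass(frozen=True)
class CultivarEffect:
    """Per-gene rhythm modulation in one cultivar: phase shift (hours)
    and/or amplitude rescaling."""

    phase_shift: float = 0.0
    amplitude_scale: float = 1.0


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth AS event expected from the generated annotation."""

    gene_id: str
    isoform_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    merged_count: int = 1


# ---------------------------------------------------------------------------
# Annotation with planted AS events
# ---------------------------------------------------------------------------

_EXON_LEN = 200
_INTRON_LEN = 300
_N_EXONS = 6
_GENE_SPACING = 40_000
_GENE_OFFSET = 15_000
_SITE_SHIFT = 60  # alternative donor/acceptor displacement (bases)


def _scaffold(idx: int, n_chroms: int, rng: np.random.Generator):
    chrom = f"Chr{idx % n_chroms + 1:02d}"
    start = _GENE_OFFSET + (idx // n_chroms) * _GENE_SPACING
    exons = [
        (start + i * (_EXON_LEN + _INTRON_LEN),
         start + i * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN)
        for i in range(_N_EXONS)
    ]
    strand = "+" if rng.integers(2) == 0 else "-"
    return chrom, strand, exons


def _plant(gene_id, chrom, strand, exons, etype, rng):
    """Build (isoform exon lists, truth events) for one planted event."""
    ref = list(exons)
    introns = [(a[1], b[0]) for a, b in zip(ref, ref[1:])]
    tid_ref, tid_alt = f"{gene_id}.1", f"{gene_id}.2"
    truth: list[tuple[str, str, int, int, int]] = []  # (iso, type, start, end, count)

    if etype == "IR":
        j = int(rng.integers(1, 4))
        alt = ref[:j] + [(ref[j][0], ref[j + 1][1])] + ref[j + 2:]
        truth.append((tid_alt, "IR", introns[j][0], introns[j][1], 1))
    elif etype == "ES":
        r = int(rng.integers(1, 3))
        j = int(rng.integers(1, 5 - r))
        alt = ref[:j] + ref[j + r:]
        truth.append((tid_alt, "ES", ref[j][0], ref[j + r - 1][1], r))
    elif etype in ("AA", "AD"):
        j = int(rng.integers(1, 4))
        # acceptor is the intron boundary next to the transcription-
        # downstream exon; donor the one next to the upstream exon
        move_right = (etype == "AA") == (strand == "+")
        alt = list(ref)
        if move_right:  # shift start of genomic-right exon inward
            s, e = ref[j + 1]
            alt[j + 1] = (s + _SITE_SHIFT, e)
        else:  # shift end of genomic-left exon inward
            s, e = ref[j]
            alt[j] = (s, e - _SITE_SHIFT)
        alt_introns = [(a[1], b[0]) for a, b in zip(alt, alt[1:])]
        truth.append((tid_alt, etype, alt_introns[j][0], alt_introns[j][1], 1))
        truth.append((tid_ref, etype, introns[j][0], introns[j][1], 1))
    elif etype == "ME":
        j = int(rng.integers(2, 4))
        x = ref[j]
        y = (x[1] + _SITE_SHIFT, x[1] + _SITE_SHIFT + 100)
        alt = ref[:j] + [y] + ref[j + 1:]
        span = (x[0], y[1])
        truth.append((tid_alt, "ME", span[0], span[1], 1))
        truth.append((tid_ref, "ME", span[0], span[1], 1))
    elif etype == "TRAP":
        # terminal intron retention: the retaining exon is the alternative
        # isoform's FIRST exon, so no event may be reported
        alt = [(ref[0][0], ref[1][1])] + ref[2:]
        truth = []
    else:
        raise ValidationError(f"unknown planted event type {etype!r}")

    isoforms = [
        TranscriptModel.from_coords(tid_ref, gene_id, chrom, strand, ref),
        TranscriptModel.from_coords(tid_alt, gene_id, chrom, strand, alt),
    ]
    events = [
        PlantedEvent(gene_id, iso, et, chrom, s, e, strand, c)
        for iso, et, s, e, c in truth
    ]
    return isoforms, events


def generate_annotation(
    n_genes: int,
    event_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    n_chroms: int = 20,
    n_terminal_traps: int = 0,
) -> tuple[dict[str, list[TranscriptModel]], list[PlantedEvent]]:
    """Annotation with a reference isoform per gene plus, for a planted
    fraction, one alternative isoform embodying exactly one event.

    ``event_mix`` maps event type to the fraction of genes carrying it; the
    remainder are single-isoform genes. ``n_terminal_traps`` genes (taken
    from the single-isoform remainder) instead carry a terminal intron
    retention that the caller must NOT report. AA/AD/ME plants are
    intrinsically symmetric, so their truth lists one event per isoform.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    mix = dict(DEFAULT_EVENT_MIX if event_mix is None else event_mix)
    if any(f < 0 for f in mix.values()):
        raise ValidationError("event_mix fractions must be >= 0")
    if sum(mix.values()) > 1 + 1e-9:
        raise ValidationError("event_mix fractions must sum to <= 1")
    for etype in mix:
        if etype not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {etype!r}")

    rng = np.random.default_rng(seed)
    plan: list[str] = []
    for etype in EVENT_TYPES:  # fixed order for determinism
        plan.extend([etype] * int(round(mix.get(etype, 0.0) * n_genes)))
    plan = plan[:n_genes]
    n_rest = n_genes - len(plan)
    n_traps = min(n_terminal_traps, n_rest)
    plan.extend(["TRAP"] * n_traps)
    plan.extend(["NONE"] * (n_rest - n_traps))
    plan = [plan[i] for i in rng.permutation(n_genes)]

    annotation: dict[str, list[TranscriptModel]] = {}
    truth: list[PlantedEvent] = []
    for idx, etype in enumerate(plan):
        gene_id = f"g{idx + 1:05d}"
        chrom, strand, exons = _scaffold(idx, n_chroms, rng)
        if etype == "NONE":
            annotation[gene_id] = [
                TranscriptModel.from_coords(f"{gene_id}.1", gene_id, chrom, strand, exons)
            ]
        else:
            isoforms, events = _plant(gene_id, chrom, strand, exons, etype, rng)
            annotation[gene_id] = isoforms
            truth.extend(events)
    return annotation, truth


# ---------------------------------------------------------------------------
# Rhythmic expression
# ---------------------------------------------------------------------------

def _sample_keys(cultivars, timepoints, n_reps):
    return [
        SampleKey(c, int(t), r)
        for c in cultivars
        for t in timepoints
        for r in range(1, n_reps + 1)
    ]


def generate_expression(
    annotation: Mapping[str, Sequence[TranscriptModel]],
    phase_groups: Sequence[RhythmSpec] | None = None,
    cultivar_effects: Mapping[str, Mapping[str, CultivarEffect]] | None = None,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    n_reps: int = 3,
    seed: int = 0,
    cultivars: Sequence[str] = ("HX3", "ZH24"),
    gene_baseline_sigma: float = 0.3,
) -> tuple[TimeSeriesMatrix, TimeSeriesMatrix, dict[str, int]]:
    """Cosine-rhythmic expression for every transcript and gene.

    Genes are assigned cyclically to the phase groups; each transcript's
    expected abundance is its isoform weight times
    ``baseline + amplitude * cos(2*pi*(t - acrophase)/24)``, multiplied by
    independent log-normal noise ``exp(N(0, noise_sd^2))`` per sample.
    ``cultivar_effects[cultivar][gene]`` shifts the acrophase (phase
    modulation) and/or rescales the amplitude (amplitude modulation). The
    gene matrix is exactly the column sum of its transcripts' rows.
    Returns (gene matrix, transcript matrix, gene -> phase-group index).
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    groups = list(default_phase_groups() if phase_groups is None else phase_groups)
    effects = cultivar_effects or {}
    rng = np.random.default_rng(seed)
    keys = _sample_keys(cultivars, timepoints, n_reps)
    n_samples = len(keys)
    times = np.array([k.timepoint for k in keys], dtype=float)
    cults = [k.cultivar for k in keys]

    gene_ids = sorted(annotation)
    truth = {g: i % len(groups) for i, g in enumerate(gene_ids)}

    tx_rows: list[np.ndarray] = []
    tx_ids: list[str] = []
    gene_rows: list[np.ndarray] = []
    for g in gene_ids:
        spec = groups[truth[g]]
        scale = math.exp(rng.normal(0.0, gene_baseline_sigma)) if gene_baseline_sigma else 1.0
        isoforms = sorted(annotation[g], key=lambda t: t.transcript_id)
        k = len(isoforms)
        weights = rng.dirichlet([4.0] + [1.0] * (k - 1)) if k > 1 else np.ones(1)
        mean = np.empty(n_samples)
        for s in range(n_samples):
            eff = effects.get(cults[s], {}).get(g, CultivarEffect())
            mean[s] = spec.mean_at(times[s], eff.phase_shift, eff.amplitude_scale)
        mean *= scale
        gene_total = np.zeros(n_samples)
        for w, iso in zip(weights, isoforms):
            noise = (
                np.exp(rng.normal(0.0, spec.noise_sd, size=n_samples))
                if spec.noise_sd > 0
                else np.ones(n_samples)
            )
            row = w * mean * noise
            tx_ids.append(iso.transcript_id)
            tx_rows.append(row)
            gene_total = gene_total + row
        gene_rows.append(gene_total)

    gene_tsm = TimeSeriesMatrix.from_arrays(gene_ids, keys, np.vstack(gene_rows))
    tx_tsm = TimeSeriesMatrix.from_arrays(tx_ids, keys, np.vstack(tx_rows))
    return gene_tsm, tx_tsm, truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def generate_variants(
    annotation: Mapping[str, Sequence[TranscriptModel]],
    gene_groups: Mapping[str, str],
    enrichment: float = 3.0,
    base_rate_per_kb: float = 2.0,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Poisson-distributed variants around every gene.

    Genes labelled ``discordant`` get their per-kb rate multiplied by
    ``enrichment`` in the gene body, the U10K/U5K shells and all downstream
    shells, but NOT in the U2K/U1K shells; ``concordant`` genes keep the
    base rate everywhere.
    """
    if enrichment < 1:
        raise ValidationError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    variants: list[tuple[str, int]] = []
    unenriched = {"U2K", "U1K"}
    for gene_id in sorted(annotation):
        span = gene_span(annotation[gene_id])
        group = gene_groups.get(gene_id, "concordant")
        for label in BIN_LABELS:
            lo, hi = region_bins(span)[label]
            lo = max(lo, 0)
            if hi <= lo:
                continue
            rate = base_rate_per_kb * (hi - lo) / 1000.0
            if group == "discordant" and label not in unenriched:
                rate *= enrichment
            n = rng.poisson(rate)
            if n:
                positions = np.sort(rng.integers(lo, hi, size=n))
                variants.extend((span.chrom, int(p)) for p in positions)
    variants.sort()
    return variants


# ---------------------------------------------------------------------------
# Chromosome count tables
# ---------------------------------------------------------------------------

def generate_chromosome_counts(
    n_chroms: int = 20,
    group_acrophases: Sequence[float] = DEFAULT_GROUP_ACROPHASES,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    n_reps: int = 3,
    seed: int = 0,
    cultivar: str = "HX3",
    baseline: float = 50_000.0,
    rel_amplitude: float = 0.4,
    depth_sigma: float = 0.2,
) -> tuple[TimeSeriesMatrix, dict[str, int]]:
    """Per-chromosome mapped-read counts in planted phase groups.

    Chromosomes are assigned cyclically to the acrophase groups; expected
    counts follow ``depth_s * base_c * (1 + rel_amplitude*cos(...))`` with
    Poisson sampling, where ``depth_s`` is a per-sample log-normal
    sequencing-depth factor and ``base_c`` a per-chromosome size factor.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"Chr{i + 1:02d}" for i in range(n_chroms)]
    truth = {c: i % len(group_acrophases) for i, c in enumerate(chroms)}
    keys = _sample_keys([cultivar], timepoints, n_reps)
    times = np.array([k.timepoint for k in keys], dtype=float)
    depth = np.exp(rng.normal(0.0, depth_sigma, size=len(keys)))
    base = baseline * np.exp(rng.normal(0.0, 0.3, size=n_chroms))
    values = np.empty((n_chroms, len(keys)))
    for i, chrom in enumerate(chroms):
        acro = group_acrophases[truth[chrom]]
        mean = base[i] * (
            1.0 + rel_amplitude * np.cos(2 * np.pi * (times - acro) / PERIOD_H)
        )
        values[i] = rng.poisson(np.maximum(mean * depth, 0.0))
    return TimeSeriesMatrix.from_arrays(chroms, keys, values), truth


def generate_blocked_chromosome_counts(
    n_chroms: int = 20,
    blocks: Sequence[Sequence[int]] = ((48, 51), (54, 57, 60), (63, 66, 69)),
    n_reps: int = 3,
    seed: int = 0,
    cultivar: str = "HX3",
    baseline: float = 50_000.0,
    contrast: float = 0.5,
    depth_sigma: float = 0.2,
) -> tuple[TimeSeriesMatrix, dict[int, int]]:
    """Counts whose timepoint profiles are constant within planted blocks.

    Every timepoint of one block shares the block-level expected profile
    across chromosomes, so clustering timepoints should recover the block
    partition (e.g. morning {48,51} / afternoon {54,57,60} / night
    {63,66,69}). Returns the matrix and timepoint -> block-index truth.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"Chr{i + 1:02d}" for i in range(n_chroms)]
    timepoints = [t for b in blocks for t in b]
    block_of = {int(t): bi for bi, b in enumerate(blocks) for t in b}
    keys = _sample_keys([cultivar], sorted(timepoints), n_reps)
    depth = np.exp(rng.normal(0.0, depth_sigma, size=len(keys)))
    base = baseline * np.exp(rng.normal(0.0, 0.3, size=n_chroms))
    # one-hot block boost per chromosome, cycled
    level = np.ones((n_chroms, len(blocks)))
    for i in range(n_chroms):
        level[i, i % len(blocks)] += contrast
    values = np.empty((n_chroms, len(keys)))
    for i in range(n_chroms):
        mean = np.array(
            [base[i] * level[i, block_of[k.timepoint]] for k in keys]
        )
        values[i] = rng.poisson(np.maximum(mean * depth, 0.0))
    return TimeSeriesMatrix.from_arrays(chroms, keys, values), block_of
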