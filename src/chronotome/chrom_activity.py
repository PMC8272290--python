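"""Chromosome-level activation rhythms.

A chromosome's activation at a timepoint is measured as the number of reads
mapped to it. Count tables are normalized in three steps — counts-per-million
within each sample (removes sequencing-depth differences), replicate
averaging per timepoint, per-chromosome z-standardization across timepoints —
then chromosomes and timepoints are co-clustered hierarchically (Euclidean,
average linkage): chromosomes into groups CG1..CG6 labelled by mean peak
time, timepoints into groups TG1..TG3 labelled by earliest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import TimeSeriesMatrix, ValidationError


@dataclass
class ChromosomeActivity:
    """Normalized activation matrix: chromosomes x timepoints, z-scored rows."""

    cultivar: str
    values: pd.DataFrame
    flagged_zero_variance: list[str] = field(default_factory=list)

    @property
    def chroms(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[int]:
        return list(self.values.columns)


def normalize_activity(
    counts: TimeSeriesMatrix, cultivar: str | None = None
) -> ChromosomeActivity:
    """CPM-normalize, replicate-average and row-standardize a count table."""
    if cultivar is None:
        cultivars = counts.cultivars
        if len(cultivars) != 1:
            raise ValidationError(
                f"count table holds cultivars {cultivars}; pass cultivar="
            )
        cultivar = cultivars[0]
    tsm = counts.select_cultivar(cultivar)
    totals = tsm.data.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"all-zero sample column {bad}")
    cpm = tsm.data.div(totals, axis=1) * 1e6
    by_tp = cpm.T.groupby(level="timepoint").mean().T
    by_tp = by_tp.reindex(columns=sorted(by_tp.columns))
    if by_tp.shape[1] < 2:
        raise ValidationError("need >= 2 timepoints")
    sd = by_tp.std(axis=1, ddof=1)
    flagged = list(by_tp.index[sd <= 0])
    kept = by_tp.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return ChromosomeActivity(cultivar, z, flagged)


def _cut(matrix: np.ndarray, k: int) -> np.ndarray:
    link = linkage(matrix, method="average", metric="euclidean")
    return fcluster(link, t=k, criterion="maxclust")


def cluster_chrom_time(
    activity: ChromosomeActivity, k_chrom: int = 6, k_time: int = 3
) -> tuple[dict[str, str], dict[int, str]]:
    """Agglomerative co-clustering of chromosomes and timepoints.

    Chromosome groups are labelled CG1..CGk by ascending group mean peak
    timepoint; timepoint groups TG1..TGk by ascending earliest member.
    Deterministic (no random initialisation).
    """
    vals = activity.values
    if len(vals) < k_chrom:
        raise ValidationError(f"{len(vals)} chromosomes < k_chrom={k_chrom}")
    if vals.shape[1] < k_time:
        raise ValidationError(f"{vals.shape[1]} timepoints < k_time={k_time}")

    chrom_raw = _cut(vals.to_numpy(), k_chrom)
    peaks = vals.idxmax(axis=1).astype(float)
    group_ids = sorted(
        set(chrom_raw),
        key=lambda c: (peaks[chrom_raw == c].mean(), min(vals.index[chrom_raw == c])),
    )
    chrom_labels = {}
    for pos, c in enumerate(group_ids):
        for chrom in vals.index[chrom_raw == c]:
            chrom_labels[chrom] = f"CG{pos + 1}"

    time_raw = _cut(vals.to_numpy().T, k_time)
    tps = np.array(vals.columns)
    tgroup_ids = sorted(set(time_raw), key=lambda c: tps[time_raw == c].min())
    time_labels = {}
    for pos, c in enumerate(tgroup_ids):
        for tp in tps[time_raw == c]:
            time_labels[int(tp)] = f"TG{pos + 1}"
    return chrom_labels, time_labels
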