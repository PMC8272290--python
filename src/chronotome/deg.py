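"""Per-timepoint differential expression between cultivars.

Because every gene oscillates, differential expression between two genotypes
depends strongly on when samples are taken. This module calls DEGs at a
single timepoint (Welch's t-test on log2(TPM+1) with Benjamini-Hochberg
adjustment across genes), simulates the 12-hour merged-sampling strategy
(replicate-paired mean of samples 12 h apart, e.g. the 48/60 HPE merged
sample), and summarizes how little DEG sets overlap across timepoints
(pairwise intersections and Venn partitions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import TimeSeriesMatrix, ValidationError


def call_degs(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test per gene between two replicate tables (genes x reps).

    Expression is log2(x+1)-transformed; ``log2fc`` is cultivar B minus A on
    that scale; p-values are BH-adjusted across genes; a gene is a DEG when
    ``fdr <= alpha`` and ``|log2fc| >= lfc_min``. Genes with zero variance
    in both groups get p=1 when the means are equal (no evidence) and p=0
    otherwise (means differ exactly).
    """
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates per group")
    if not expr_a.index.equals(expr_b.index):
        expr_b = expr_b.reindex(expr_a.index)
        if expr_b.isna().any().any():
            raise ValidationError("gene universes differ between groups")
    la = np.log2(expr_a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(expr_b.to_numpy(dtype=float) + 1.0)
    res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    degenerate = np.isnan(pvals)
    pvals[degenerate & (log2fc == 0)] = 1.0
    pvals[degenerate & (log2fc != 0)] = 0.0
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_deg": (fdr <= alpha) & (np.abs(log2fc) >= lfc_min),
        },
        index=expr_a.index,
    )
    out.index.name = "gene_id"
    return out


def call_degs_at_timepoint(
    matrix: TimeSeriesMatrix,
    cultivar_a: str,
    cultivar_b: str,
    timepoint: int,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    return call_degs(
        matrix.replicate_vectors(cultivar_a, timepoint),
        matrix.replicate_vectors(cultivar_b, timepoint),
        alpha=alpha,
        lfc_min=lfc_min,
    )


@dataclass
class MergedSamples:
    """Replicate-paired 12-h merged samples, one table per cultivar."""

    key: str  # e.g. "48/60"
    timepoints: tuple[int, int]
    per_cultivar: dict[str, pd.DataFrame]  # cultivar -> genes x replicates


def merge_12h(
    matrix: TimeSeriesMatrix, timepoint: int, spacing: int = 12
) -> MergedSamples:
    """Combine samples ``spacing`` hours apart into one merged sample.

    Replicate i at ``timepoint`` pairs with replicate i at
    ``timepoint+spacing``; the merged value is the arithmetic mean of the
    pair (preserving the TPM scale). Both timepoints must exist on the
    matrix grid and must differ.
    """
    if spacing == 0:
        raise ValidationError("cannot merge a timepoint with itself")
    partner = timepoint + spacing
    grid = matrix.timepoints
    if timepoint not in grid or partner not in grid:
        raise ValidationError(
            f"merged pair ({timepoint}, {partner}) not on grid {grid}"
        )
    per_cultivar = {}
    for cultivar in matrix.cultivars:
        first = matrix.replicate_vectors(cultivar, timepoint)
        second = matrix.replicate_vectors(cultivar, partner)
        reps = sorted(set(first.columns) & set(second.columns))
        if not reps:
            raise ValidationError(f"no paired replicates for cultivar {cultivar}")
        per_cultivar[cultivar] = (first[reps] + second[reps]) / 2.0
    return MergedSamples(f"{timepoint}/{partner}", (timepoint, partner), per_cultivar)


def mergeable_pairs(
    grid: Sequence[int], spacing: int = 12
) -> list[tuple[int, int]]:
    """All (t, t+spacing) pairs constructible on a timepoint grid."""
    gset = set(grid)
    return [(t, t + spacing) for t in sorted(gset) if t + spacing in gset]


def deg_overlap(
    deg_sets: Mapping[str, set],
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Pairwise intersection matrix and Venn partition of DEG sets.

    The Venn partition (all 2^k - 1 exclusive regions) is computed for
    k <= 4 sets; the pairwise table for any k. Region keys are sorted
    tuples of the set names whose intersection (minus all others) the
    count describes.
    """
    names = sorted(deg_sets)
    pairwise = pd.DataFrame(
        [
            [len(deg_sets[a] & deg_sets[b]) for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    venn: dict[tuple[str, ...], int] = {}
    if len(names) <= 4:
        for r in range(1, len(names) + 1):
            for inside in combinations(names, r):
                region = set.intersection(*(deg_sets[n] for n in inside))
                for other in names:
                    if other not in inside:
                        region = region - deg_sets[other]
                venn[tuple(inside)] = len(region)
    return pairwise, venn
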