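"""Phase clustering of gene time-series and cosinor phase/amplitude fits.

Per-gene expression profiles (replicates averaged per timepoint, optionally
log2-transformed, then z-scored) are partitioned by k-means into six phase
clusters named C1-C6 by their centroid peak time following the convention
C1 = dawn (H48), C2 = day (H51-57), C3 = dusk (H60), C5/C6/C4 = early/mid/
late night (H63/H66/H69). Single-component cosinor fits
``x(t) = M + a*cos(2*pi*t/P) + b*sin(2*pi*t/P)`` give each gene a mesor,
amplitude and acrophase, and per-gene circular phase differences and
amplitude ratios between cultivars quantify phase modulation vs amplitude
modulation of a rhythm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import PERIOD_H, TimeSeriesMatrix, ValidationError

#: Phase-name buckets of the default sampling grid.
PHASE_NAMES: dict[int, str] = {
    48: "dawn",
    51: "day",
    54: "day",
    57: "day",
    60: "dusk",
    63: "early-night",
    66: "mid-night",
    69: "late-night",
}

#: Cluster labels in centroid-peak-time order (C4 is the LATE-night cluster).
_LABELS_BY_PEAK_ORDER: tuple[str, ...] = ("C1", "C2", "C3", "C5", "C6", "C4")


@dataclass
class ScaledProfiles:
    """Replicate-averaged, z-scored profiles (genes x timepoints).

    Zero-variance genes are excluded from ``profiles`` and listed in
    ``flagged_zero_variance``.
    """

    cultivar: str
    profiles: pd.DataFrame
    flagged_zero_variance: list[str] = field(default_factory=list)

    @property
    def timepoints(self) -> list[int]:
        return list(self.profiles.columns)


def scale_profiles(
    matrix: TimeSeriesMatrix,
    cultivar: str,
    log_transform: bool = True,
) -> ScaledProfiles:
    """Average replicates per timepoint and z-standardize each gene.

    ``log_transform`` applies log2(x+1) before standardization (expression
    is typically clustered on log scale). Standardization uses the sample
    standard deviation; genes with zero variance are flagged and excluded.
    """
    prof = matrix.replicate_mean(cultivar)
    if prof.shape[1] < 2:
        raise ValidationError("need >= 2 timepoints to scale profiles")
    if prof.isna().any().any():
        missing = prof.index[prof.isna().any(axis=1)][0]
        raise ValidationError(f"gene {missing!r} lacks a timepoint measurement")
    if log_transform:
        prof = np.log2(prof + 1.0)
    sd = prof.std(axis=1, ddof=1)
    flagged = list(prof.index[sd <= 0])
    kept = prof.loc[sd > 0]
    scaled = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return ScaledProfiles(cultivar, scaled, flagged)


@dataclass
class ClusterAssignment:
    """Gene -> phase-cluster labels of one cultivar, with centroids."""

    cultivar: str
    labels: dict[str, str]
    centroids: pd.DataFrame  # label x timepoint
    phase_labels: dict[str, int]  # label -> centroid peak timepoint


def _peak_timepoint(values: pd.Series) -> int:
    """Argmax timepoint; ties break to the earliest timepoint."""
    best = values.idxmax()  # pandas idxmax returns first occurrence
    return int(best)


def cluster_genes(
    profiles: ScaledProfiles,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterAssignment:
    """K-means partition of scaled profiles into k phase clusters.

    Best of ``n_restarts`` random initialisations, deterministic under a
    fixed seed. For k=6, clusters are renamed C1-C6 by centroid peak time
    (C1 dawn ... C4 late night); other k get C1..Ck in peak-time order.
    """
    data = profiles.profiles
    if len(data) < k:
        raise ValidationError(f"{len(data)} profiles < k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(data.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=data.columns)

    order = sorted(
        range(k),
        key=lambda i: (
            _peak_timepoint(centroids.iloc[i]),
            tuple(centroids.iloc[i]),
        ),
    )
    if k == 6:
        names = list(_LABELS_BY_PEAK_ORDER)
    else:
        names = [f"C{i + 1}" for i in range(k)]
    rename = {raw_idx: names[pos] for pos, raw_idx in enumerate(order)}

    labels = {g: rename[c] for g, c in zip(data.index, raw)}
    centroids.index = [rename[i] for i in range(k)]
    centroids = centroids.loc[[names[pos] for pos in range(k)]]
    phase_labels = {
        lab: _peak_timepoint(centroids.loc[lab]) for lab in centroids.index
    }
    return ClusterAssignment(profiles.cultivar, labels, centroids, phase_labels)


def label_cluster_phases(assignment: ClusterAssignment) -> dict[str, str]:
    """Map each cluster label to its phase name from the centroid peak."""
    out = {}
    for lab, peak in assignment.phase_labels.items():
        if peak not in PHASE_NAMES:
            raise ValidationError(f"peak timepoint {peak} has no phase-name bucket")
        out[lab] = PHASE_NAMES[peak]
    return out


def cross_cultivar_intersection(
    assign_a: ClusterAssignment,
    assign_b: ClusterAssignment,
) -> tuple[pd.DataFrame, float]:
    """Cluster-membership contingency table between two cultivars.

    Uses the shared gene universe; returns the labelA x labelB count table
    and the same-cluster fraction (trace/total) as a percentage rounded
    half-up to one decimal.
    """
    shared = sorted(set(assign_a.labels) & set(assign_b.labels))
    if not shared:
        raise ValidationError("assignments share no genes")
    la = pd.Series({g: assign_a.labels[g] for g in shared})
    lb = pd.Series({g: assign_b.labels[g] for g in shared})
    table = pd.crosstab(la, lb)
    order = sorted(set(table.index) | set(table.columns))
    table = table.reindex(index=order, columns=order, fill_value=0)
    return table, same_cluster_fraction(table)


def same_cluster_fraction(table: pd.DataFrame) -> float:
    """Diagonal share of a square contingency table, in percent (1 d.p.)."""
    diag = sum(
        table.loc[lab, lab] for lab in table.index if lab in table.columns
    )
    total = table.to_numpy().sum()
    if total <= 0:
        raise ValidationError("empty contingency table")
    pct = Decimal(int(diag)) * 100 / Decimal(int(total))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CosinorFit:
    """Least-squares single-harmonic fit of one profile."""

    mesor: float
    amplitude: float
    acrophase: float  # peak time in [0, period) h; meaningless if flagged_flat
    rss: float
    flagged_flat: bool
    period: float = PERIOD_H


def cosinor_fit(
    timepoints: Sequence[float],
    values: Sequence[float],
    period: float = PERIOD_H,
) -> CosinorFit:
    """Closed-form cosinor: x(t) = M + a*cos(2*pi*t/P) + b*sin(2*pi*t/P).

    Amplitude = sqrt(a^2+b^2); acrophase = (P/2*pi)*atan2(b, a) mod P, the
    time at which the fitted cosine peaks. Profiles with amplitude below
    1e-9 x |mesor| are flagged flat (acrophase undefined).
    """
    t = np.asarray(timepoints, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValidationError("cosinor needs >= 4 timepoints")
    if t.max() - t.min() < period / 2:
        raise ValidationError("timepoints must span >= half a period")
    w = 2 * np.pi * t / period
    design = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    mesor, a, b = (float(c) for c in coef)
    amplitude = math.hypot(a, b)
    rss = float(np.sum((x - design @ coef) ** 2))
    flat = amplitude < max(1e-9 * abs(mesor), 1e-12)
    acrophase = (period / (2 * np.pi) * math.atan2(b, a)) % period
    return CosinorFit(mesor, amplitude, acrophase, rss, flat, period)


def fit_profiles(
    profiles: pd.DataFrame, period: float = PERIOD_H
) -> dict[str, CosinorFit]:
    """Cosinor fit per row of a features x timepoints table."""
    t = [float(c) for c in profiles.columns]
    return {
        str(g): cosinor_fit(t, profiles.loc[g].to_numpy(), period)
        for g in profiles.index
    }


def circular_phase_difference(a: float, b: float, period: float = PERIOD_H) -> float:
    """Signed circular difference b - a, wrapped into (-period/2, period/2]."""
    d = (b - a) % period
    if d > period / 2:
        d -= period
    return d


def compare_phase_amplitude(
    fits_a: Mapping[str, CosinorFit],
    fits_b: Mapping[str, CosinorFit],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene circular acrophase shift (B vs A, hours) and amplitude ratio.

    Rows where either fit is flagged flat are marked ``flagged`` (their
    phase difference is not interpretable).
    """
    if genes is None:
        genes = sorted(set(fits_a) & set(fits_b))
    rows = []
    for g in genes:
        fa, fb = fits_a[g], fits_b[g]
        flagged = fa.flagged_flat or fb.flagged_flat
        rows.append(
            {
                "gene_id": g,
                "delta_acrophase_h": (
                    float("nan")
                    if flagged
                    else circular_phase_difference(fa.acrophase, fb.acrophase, fa.period)
                ),
                "amplitude_ratio": (
                    float("nan") if fa.amplitude == 0 else fb.amplitude / fa.amplitude
                ),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
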