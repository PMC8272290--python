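import numpy as np
import pytest

from chronotome.io_formats import SampleKey, TimeSeriesMatrix, TranscriptModel


@pytest.fixture
def two_exon_gene():
    """Single-isoform, two-exon gene on the plus strand."""
    return [
        TranscriptModel.from_coords("t1", "g1", "chr1", "+", [(100, 200), (400, 500)])
    ]


@pytest.fixture
def five_exon_layout():
    """Reference exon layout E1..E5 used by skipping/retention constructions."""
    return [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]


def make_matrix(feature_rows, cultivars=("HX3",), timepoints=(48, 51, 54, 57, 60, 63, 66, 69), n_reps=1):
    """Tiny TimeSeriesMatrix from {feature: per-timepoint values} (replicated)."""
    keys = [
        SampleKey(c, t, r)
        for c in cultivars
        for t in timepoints
        for r in range(1, n_reps + 1)
    ]
    rows = []
    for _, values in feature_rows.items():
        row = []
        for c in cultivars:
            for v in values:
                row.extend([v] * n_reps)
        rows.append(row)
    return TimeSeriesMatrix.from_arrays(list(feature_rows), keys, np.array(rows, dtype=float))
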