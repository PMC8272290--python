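#!/usr/bin/env python
"""Call DEGs between the cultivars per timepoint and for 12-h merged samples.

Runs Welch/BH differential expression at each of the eight timepoints, then
for the four constructible 12-h merged pairs (48/60, 51/63, 54/66, 57/69),
and summarizes how strongly DEG sets depend on sampling time: per-timepoint
DEG counts, pairwise overlaps, and the Venn partition of the first four
timepoints and of the merged pairs.
"""

import argparse
from pathlib import Path

import pandas as pd

from chronotome.deg import (
    call_degs,
    call_degs_at_timepoint,
    deg_overlap,
    merge_12h,
    mergeable_pairs,
)
from chronotome.io_formats import read_matrix

ROOT = Path(__file__).resolve().parents[1]


def venn_frame(venn: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [("&".join(k), v) for k, v in sorted(venn.items())],
        columns=["region", "count"],
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "scratch" / "sim")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--lfc-min", type=float, default=1.0)
    args = ap.parse_args()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    gene_m = read_matrix(args.sim / "gene_expression.tsv")
    ca, cb = sorted(gene_m.cultivars)

    deg_sets: dict[str, set] = {}
    rows = []
    for tp in gene_m.timepoints:
        out = call_degs_at_timepoint(gene_m, ca, cb, tp, args.alpha, args.lfc_min)
        degs = set(out.index[out["is_deg"]])
        deg_sets[f"H{tp}"] = degs
        rows.append({"timepoint": tp, "n_deg": len(degs)})
    pd.DataFrame(rows).to_csv(res / "05_deg_counts.tsv", sep="\t", index=False)

    pairwise, venn = deg_overlap({k: deg_sets[k] for k in list(deg_sets)[:4]})
    pairwise.to_csv(res / "05_deg_overlap_timepoints.tsv", sep="\t")
    venn_frame(venn).to_csv(res / "05_deg_venn_timepoints.tsv", sep="\t", index=False)

    merged_sets: dict[str, set] = {}
    for t, _partner in mergeable_pairs(gene_m.timepoints):
        merged = merge_12h(gene_m, t)
        out = call_degs(
            merged.per_cultivar[ca], merged.per_cultivar[cb], args.alpha, args.lfc_min
        )
        merged_sets[merged.key] = set(out.index[out["is_deg"]])
    _, venn_merged = deg_overlap(merged_sets)
    venn_frame(venn_merged).to_csv(res / "05_deg_venn_merged.tsv", sep="\t", index=False)

    consistent = set.intersection(*deg_sets.values()) if deg_sets else set()
    print(f"DEGs per timepoint: { {k: len(v) for k, v in deg_sets.items()} }")
    print(f"DEGs per merged pair: { {k: len(v) for k, v in merged_sets.items()} }")
    print(f"genes DE at ALL timepoints: {len(consistent)}")


if __name__ == "__main__":
    main()
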