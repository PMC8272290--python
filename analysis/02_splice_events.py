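#!/usr/bin/env python
"""Call alternative-splicing events and quantify them over the time series.

Reads the simulated annotation and transcript expression, builds each gene's
composite model, calls events, and writes: the event table, the AS status
census, event-type shares (overall and per representative transcript), the
per-sample event-expression series and the genome-wide AS ratio in both
transcript and event modes.
"""

import argparse
from pathlib import Path

import pandas as pd

from chronotome.io_formats import read_gtf, read_matrix
from chronotome.splice_events import (
    as_ratio_series,
    classify_annotation,
    event_expression_series,
    events_to_frame,
    event_type_shares,
    representative_event_counts,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=ROOT / "scratch" / "sim")
    args = ap.parse_args()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    annotation = read_gtf(args.sim / "annotation.gtf")
    tx_m = read_matrix(args.sim / "transcript_expression.tsv")

    classified = classify_annotation(annotation)
    all_events = [e for c in classified.values() for e in c.events]
    events_to_frame(all_events).to_csv(res / "02_events.tsv", sep="\t", index=False)

    n_as = sum(1 for c in classified.values() if c.status == "AS")
    census = pd.Series(
        {"n_genes": len(classified), "n_AS": n_as, "n_no_AS": len(classified) - n_as}
    )
    census.to_csv(res / "02_as_census.tsv", sep="\t", header=False)

    type_counts: dict[str, int] = {}
    for e in all_events:
        type_counts[e.event_type] = type_counts.get(e.event_type, 0) + 1
    shares = event_type_shares(type_counts)

    rep_counts: dict[str, int] = {}
    for gene_id, isoforms in annotation.items():
        for etype, n in representative_event_counts(isoforms, tx_m).items():
            rep_counts[etype] = rep_counts.get(etype, 0) + n
    pd.DataFrame(
        {"count": pd.Series(type_counts), "share_pct": pd.Series(shares),
         "representative_count": pd.Series(rep_counts)}
    ).rename_axis("type").to_csv(res / "02_event_type_shares.tsv", sep="\t")

    ev_expr = event_expression_series(all_events, tx_m)
    ev_expr.columns = ["%s_H%d_R%d" % c for c in ev_expr.columns]
    ev_expr.rename_axis("type").to_csv(res / "02_event_expression.tsv", sep="\t")

    for mode in ("transcript", "event"):
        ratio = as_ratio_series(annotation, tx_m, mode=mode)
        gw = ratio.genome_wide.copy()
        gw.index = ["%s_H%d_R%d" % c for c in gw.index]
        gw.rename("as_ratio").rename_axis("sample").to_csv(
            res / f"02_as_ratio_{mode}.tsv", sep="\t"
        )

    print(
        f"{n_as}/{len(classified)} genes with AS; events per type: {type_counts}; "
        f"shares: {shares}"
    )


if __name__ == "__main__":
    main()
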