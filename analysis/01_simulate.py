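#!/usr/bin/env python
"""Generate the synthetic study: two cultivars, 8 timepoints x 3 replicates.

Produces an annotation with planted splicing events, cosine-rhythmic gene/
transcript expression in six phase groups (with a subset of genes
phase-shifted by 12 h in ZH24 so the two cultivars cluster them
differently), variants enriched around those phase-discordant genes
(except in the 2-1 kb upstream shells), and chromosome-level count tables.
Bulky tables go to scratch/sim/; the ground-truth summaries and the full
generator configuration go to results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chronotome.io_formats import write_gtf, write_matrix, write_variants
from chronotome.synthetic import (
    CultivarEffect,
    default_phase_groups,
    generate_annotation,
    generate_blocked_chromosome_counts,
    generate_chromosome_counts,
    generate_expression,
    generate_variants,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=300)
    args = ap.parse_args()

    sim = ROOT / "scratch" / "sim"
    res = ROOT / "results"
    sim.mkdir(parents=True, exist_ok=True)
    res.mkdir(exist_ok=True)

    config = {
        "seed": args.seed,
        "n_genes": args.n_genes,
        "event_mix": {"IR": 0.15, "AA": 0.12, "AD": 0.07, "ES": 0.05, "ME": 0.01},
        "n_terminal_traps": 5,
        "phase_groups": {"baseline": 20.0, "amplitude": 10.0, "noise_sd": 0.2},
        "cultivars": ["HX3", "ZH24"],
        "n_reps": 3,
        "discordant_fraction": 0.2,
        "discordant_phase_shift_h": 12.0,
        "variant_enrichment": 3.0,
        "variant_base_rate_per_kb": 2.0,
        "chromosomes": {"n": 20, "baseline": 50000.0, "rel_amplitude": 0.4},
    }

    annotation, planted = generate_annotation(
        args.n_genes,
        event_mix=config["event_mix"],
        seed=args.seed,
        n_terminal_traps=config["n_terminal_traps"],
    )
    write_gtf(annotation, sim / "annotation.gtf")

    genes = sorted(annotation)
    n_disc = int(config["discordant_fraction"] * len(genes))
    discordant = set(genes[::5][:n_disc])  # every 5th gene, across phase groups
    effects = {
        "ZH24": {
            g: CultivarEffect(phase_shift=config["discordant_phase_shift_h"])
            for g in discordant
        }
    }
    groups = default_phase_groups(**config["phase_groups"])
    gene_m, tx_m, phase_truth = generate_expression(
        annotation, groups, cultivar_effects=effects,
        n_reps=config["n_reps"], seed=args.seed + 1,
    )
    write_matrix(gene_m, sim / "gene_expression.tsv")
    write_matrix(tx_m, sim / "transcript_expression.tsv")

    gene_groups = {
        g: ("discordant" if g in discordant else "concordant") for g in genes
    }
    variants = generate_variants(
        annotation, gene_groups,
        enrichment=config["variant_enrichment"],
        base_rate_per_kb=config["variant_base_rate_per_kb"],
        seed=args.seed + 2,
    )
    write_variants(variants, sim / "variants.tsv")

    chrom_m, chrom_truth = generate_chromosome_counts(
        n_chroms=config["chromosomes"]["n"],
        baseline=config["chromosomes"]["baseline"],
        rel_amplitude=config["chromosomes"]["rel_amplitude"],
        seed=args.seed + 3,
    )
    write_matrix(chrom_m, sim / "chromosome_counts.tsv")
    blocked_m, _ = generate_blocked_chromosome_counts(seed=args.seed + 4)
    write_matrix(blocked_m, sim / "chromosome_counts_blocked.tsv")

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "phase_group": [phase_truth[g] for g in genes],
            "cluster_concordance": [gene_groups[g] for g in genes],
            "n_isoforms": [len(annotation[g]) for g in genes],
        }
    )
    truth.to_csv(res / "01_gene_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (e.gene_id, e.isoform_id, e.event_type, e.start, e.end, e.merged_count)
            for e in planted
        ],
        columns=["gene_id", "transcript_id", "type", "start", "end", "merged_count"],
    ).to_csv(res / "01_planted_events.tsv", sep="\t", index=False)
    pd.Series(chrom_truth, name="phase_group").rename_axis("chrom").to_csv(
        res / "01_chromosome_truth.tsv", sep="\t"
    )
    with open(res / "01_simulation_config.json", "w") as fh:
        json.dump(config, fh, indent=2)

    print(f"simulated {len(genes)} genes ({len(planted)} planted events, "
          f"{len(discordant)} phase-discordant in ZH24), {len(variants)} variants, "
          f"{config['chromosomes']['n']} chromosomes -> {sim}")


if __name__ == "__main__":
    main()
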