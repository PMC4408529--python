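#!/usr/bin/env python
"""Gene-content structure of the simulated collection.

Builds the genome x pham table, counts orphams (phams with a single gene
in the whole dataset — the signature of recently acquired genes), computes
per-genome orpham proportions, the all-pairs shared-pham percentage matrix
(heatmap input) and its Nexus distance export for split-network viewers.

Reads  results/population/assignments.tsv
Writes results/gene_content/{pham_table.tsv, orpham_fractions.tsv,
       shared_pham_matrix.tsv, gene_content.nex, summary.json}
"""

import argparse
import json
from pathlib import Path

from phagepan import (
    build_pham_table,
    mean_genes_per_pham,
    orpham_fraction_per_genome,
    orphams,
    read_gene_assignments,
    shared_pham_matrix,
    write_nexus_distances,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--assignments", type=Path,
                        default=ROOT / "results" / "population" / "assignments.tsv")
    args = parser.parse_args()

    out = ROOT / "results" / "gene_content"
    out.mkdir(parents=True, exist_ok=True)

    table = build_pham_table(read_gene_assignments(args.assignments))
    table.write_tsv(out / "pham_table.tsv")

    orpham_set = orphams(table)
    orpham_pct = 100 * len(orpham_set) / table.n_phams
    fractions = orpham_fraction_per_genome(table)
    with open(out / "orpham_fractions.tsv", "w") as fh:
        fh.write("genome\torpham_fraction\n")
        for g in table.genomes:
            fh.write(f"{g}\t{fractions[g]:.4f}\n")

    shared = shared_pham_matrix(table)
    shared.write_tsv(out / "shared_pham_matrix.tsv")
    write_nexus_distances(shared, out / "gene_content.nex")

    summary = {
        "n_genomes": table.n_genomes,
        "n_phams": table.n_phams,
        "total_genes": table.total_genes,
        "mean_genes_per_pham": round(mean_genes_per_pham(table), 2),
        "n_orphams": len(orpham_set),
        "orpham_pct_of_phams": round(orpham_pct, 1),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    print(f"{table.total_genes} genes assembled into {table.n_phams} phams "
          f"({summary['mean_genes_per_pham']} genes/pham)")
    print(f"{len(orpham_set)} orphams = {orpham_pct:.0f}% of phams")
    top = sorted(fractions.items(), key=lambda kv: -kv[1])[:5]
    print("highest orpham fractions:",
          ", ".join(f"{g}={v:.2f}" for g, v in top))
    print(f"wrote pham table, orpham fractions, shared matrix and Nexus to {out}/")


if __name__ == "__main__":
    main()
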