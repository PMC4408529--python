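#!/usr/bin/env python
"""Generate the synthetic phage collection every later analysis consumes.

A clustered population of 627 genomes (20 clusters with sizes spanning
2-232 plus 8 singletons, matching the uneven cluster-size profile of a
large sequenced phage collection), with a shared accessory/global gene
pool and a constant influx of 2.5 novel single-copy phams per genome.

Writes results/population/{assignments.tsv, truth.json, config.yaml}.
"""

import argparse
import json
from pathlib import Path

from phagepan import build_pham_table, generate_population, table1_like
from phagepan.pham_core import write_gene_assignments

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--size-scale", type=float, default=1.0,
                        help="shrink cluster sizes proportionally for quick runs")
    args = parser.parse_args()

    out = ROOT / "results" / "population"
    out.mkdir(parents=True, exist_ok=True)

    config = table1_like(seed=args.seed, size_scale=args.size_scale)
    population = generate_population(config)
    table = build_pham_table(population.assignments)

    write_gene_assignments(population.assignments, out / "assignments.tsv",
                           header_comment=f"table1-like seed={args.seed}")
    (out / "truth.json").write_text(
        json.dumps(population.truth, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")

    n_clusters = len({c for c in population.truth["cluster_of"].values()})
    print(f"generated {table.n_genomes} genomes in {n_clusters} clusters")
    print(f"  {table.total_genes} genes over {table.n_phams} phams "
          f"({table.total_genes / table.n_phams:.1f} genes/pham)")
    print(f"  {population.truth['n_influx_phams']} novel influx phams "
          f"(configured rate {config.influx_rate}/genome)")
    print(f"wrote {out}/assignments.tsv, truth.json, config.yaml")


if __name__ == "__main__":
    main()
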