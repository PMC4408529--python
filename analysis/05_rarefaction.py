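#!/usr/bin/env python
"""Rarefaction curves: whole collection and the two largest clusters.

Monte-Carlo accumulation curves of distinct phams (10,000 random genome
orderings) for the full simulated collection and, independently, for its
two largest clusters — the within-cluster curves ask whether gene influx
is a collection-level artifact or visible inside single clusters too.

Reads  results/population/{assignments.tsv, truth.json}
Writes results/rarefaction/{all.tsv, cluster_<label>.tsv}
"""

import argparse
import json
import time
from pathlib import Path

from phagepan import build_pham_table, rarefaction, read_gene_assignments

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--iterations", type=int, default=10_000)
    parser.add_argument("--population-dir", type=Path,
                        default=ROOT / "results" / "population")
    args = parser.parse_args()

    out = ROOT / "results" / "rarefaction"
    out.mkdir(parents=True, exist_ok=True)

    table = build_pham_table(
        read_gene_assignments(args.population_dir / "assignments.tsv"))
    cluster_of = json.loads(
        (args.population_dir / "truth.json").read_text())["cluster_of"]
    members: dict[str, list[str]] = {}
    for genome, label in cluster_of.items():
        members.setdefault(label, []).append(genome)

    t0 = time.time()
    curve = rarefaction(table, iterations=args.iterations, seed=args.seed)
    curve.write_tsv(out / "all.tsv")
    print(f"all {curve.n_genomes} genomes: {curve.mean_phams[-1]:.0f} phams "
          f"total; mean new phams over the last 10% of sampling: "
          f"{curve.mean_new_phams[-curve.n_genomes // 10:].mean():.2f}/genome "
          f"({args.iterations} iterations, {time.time() - t0:.1f}s)")

    largest = sorted(members, key=lambda lab: -len(members[lab]))[:2]
    for label in largest:
        sub = rarefaction(table, iterations=args.iterations,
                          seed=args.seed, genomes=sorted(members[label]))
        sub.write_tsv(out / f"cluster_{label}.tsv")
        tail = sub.mean_new_phams[-max(2, sub.n_genomes // 10):].mean()
        print(f"cluster {label} ({sub.n_genomes} genomes): "
              f"{sub.mean_phams[-1]:.0f} phams; tail new phams {tail:.2f}/genome")

    print(f"wrote curves to {out}/")


if __name__ == "__main__":
    main()
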