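#!/usr/bin/env python
"""Closed vs open pangenome: hyperbola and hyperbola-plus-influx fits.

Fits both models to each rarefaction curve from the previous step
(Hanes-Woolf regression on the first half of sample sizes).  A closed
gene pool should be fully described by the saturating hyperbola; a
population under constant gene influx is not — the open model's linear
term, the per-genome influx rate, captures what the hyperbola misses.

Reads  results/rarefaction/*.tsv
Writes results/models/fits.json
"""

import argparse
import json
from pathlib import Path

from phagepan import estimate_c_phage, fit_closed_model, fit_open_model
from phagepan.rarefaction import RarefactionResult

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fit-fraction", type=float, default=0.5)
    parser.add_argument("--curves-dir", type=Path,
                        default=ROOT / "results" / "rarefaction")
    args = parser.parse_args()

    out = ROOT / "results" / "models"
    out.mkdir(parents=True, exist_ok=True)

    fits = {}
    for path in sorted(args.curves_dir.glob("*.tsv")):
        curve = RarefactionResult.read_tsv(path)
        name = path.stem
        closed = fit_closed_model(curve, args.fit_fraction)
        opened = fit_open_model(curve, args.fit_fraction)
        c_tail = estimate_c_phage(curve)
        fits[name] = {
            "n_genomes": curve.n_genomes,
            "closed": {"pham_max": round(closed.pham_max, 1),
                       "k_m": round(closed.k_m, 2), "r": round(closed.r, 5)},
            "open": {"c_phage": round(opened.c_phage, 3),
                     "pham_max": round(opened.pham_max, 1),
                     "k_m": round(opened.k_m, 2), "r": round(opened.r, 5)},
            "c_tail_estimate": round(c_tail, 3),
        }
        print(f"{name} ({curve.n_genomes} genomes):")
        print(f"  closed hyperbola: Pham_Max={closed.pham_max:.0f}, "
              f"K_m={closed.k_m:.1f}, r={closed.r:.4f}")
        print(f"  open model:       C={opened.c_phage:.2f} new phams/genome, "
              f"Pham_Max={opened.pham_max:.0f}, K_m={opened.k_m:.1f}, "
              f"r={opened.r:.5f}")

    (out / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    better = sum(1 for f in fits.values() if f["open"]["r"] > f["closed"]["r"])
    print(f"\nopen model correlates better on {better}/{len(fits)} curves")
    print(f"wrote {out}/fits.json")


if __name__ == "__main__":
    main()
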