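"""Nexus TAXA/DISTANCES export of shared-gene-content relationships.

Split-network software (NeighborNet and friends) consumes a Nexus file
with a distance matrix; the conventional transform used here is
``distance = 1 - shared_percent/100``, so identical gene complements are
at distance 0 and fully disjoint genomes at distance 1.
"""

from __future__ import annotations

import re

import numpy as np

from .pham_core import SharedPhamMatrix

__all__ = ["write_nexus_distances", "read_nexus_distances"]


def _quote(label: str) -> str:
    return f"'{label}'" if re.search(r"[\s();\[\]{}'\"=,]", label) else label


def write_nexus_distances(matrix: SharedPhamMatrix, path) -> None:
    """Write TAXA and DISTANCES blocks; distance(a,b) = 1 - shared/100."""
    taxa = matrix.genomes
    dist = 1.0 - np.asarray(matrix.values, dtype=float) / 100.0
    np.fill_diagonal(dist, 0.0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(taxa)};\n")
        fh.write("    TAXLABELS\n")
        for t in taxa:
            fh.write(f"        {_quote(t)}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN DISTANCES;\n")
        fh.write(f"    DIMENSIONS NTAX={len(taxa)};\n")
        fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n")
        fh.write("    MATRIX\n")
        for i, t in enumerate(taxa):
            row = " ".join(f"{d:.6f}" for d in dist[i])
            fh.write(f"        {_quote(t)} {row}\n")
        fh.write("    ;\nEND;\n")


def read_nexus_distances(path) -> SharedPhamMatrix:
    """Parse the package's own Nexus DISTANCES export back into a
    shared-percent matrix (inverse of the 1 - p/100 transform)."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    m = re.search(r"BEGIN DISTANCES;.*?MATRIX\s*(.*?);\s*END;", text,
                  re.DOTALL | re.IGNORECASE)
    if not m:
        raise ValueError("no DISTANCES matrix block found")
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            label, rest = line[1:end], line[end + 1:]
        else:
            label, _, rest = line.partition(" ")
        taxa.append(label)
        rows.append([float(v) for v in rest.split()])
    values = 100.0 * (1.0 - np.asarray(rows, dtype=float))
    return SharedPhamMatrix(taxa, values)
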