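"""Rarefaction (gene-family accumulation) curves and CLASP resampling.

The rarefaction curve asks: sampling n genomes at random without
replacement, how many distinct phams does one expect to have seen?  The
per-step increment (new phams contributed by the n-th genome) is the
quantity whose large-n plateau estimates the external gene-influx rate of
an open pangenome.

Implementation note: instead of accumulating a presence union per step,
each Monte-Carlo iteration computes, for every pham, the rank at which it
is first discovered under the random genome ordering (a grouped minimum
over the pham's member genomes).  A bincount of discovery ranks gives the
new-pham increments and their cumulative sum the accumulation curve, in
O(total presence entries) per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pham_core import PhamTable
from .diversity import clasp

__all__ = ["RarefactionResult", "ClaspResampleResult", "rarefaction", "clasp_resample"]


@dataclass
class RarefactionResult:
    """Mean/SD accumulation curve over random genome orderings.

    ``mean_phams[n-1]`` is the expected distinct-pham count after n
    genomes; ``mean_new_phams[n-1]`` the expected increment contributed by
    the n-th genome.  SDs use the population formula (divide by the number
    of iterations).
    """

    n_values: np.ndarray
    mean_phams: np.ndarray
    sd_phams: np.ndarray
    mean_new_phams: np.ndarray
    iterations: int
    seed: int | None

    @property
    def n_genomes(self) -> int:
        return int(self.n_values[-1])

    def confidence_band(self, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        """mean +/- k standard deviations (k=2 by convention)."""
        return self.mean_phams - k * self.sd_phams, self.mean_phams + k * self.sd_phams

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# iterations={self.iterations} seed={self.seed}\n")
            fh.write("n\tmean_phams\tsd_phams\tmean_new_phams\n")
            for n, m, s, d in zip(self.n_values, self.mean_phams,
                                  self.sd_phams, self.mean_new_phams):
                fh.write(f"{int(n)}\t{m:.6f}\t{s:.6f}\t{d:.6f}\n")

    @classmethod
    def read_tsv(cls, path) -> "RarefactionResult":
        import pandas as pd

        iterations, seed = 0, None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("# iterations="):
                    parts = dict(p.split("=") for p in line[2:].split())
                    iterations = int(parts["iterations"])
                    seed = None if parts.get("seed") == "None" else int(parts["seed"])
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame["n"].to_numpy(), frame["mean_phams"].to_numpy(),
                   frame["sd_phams"].to_numpy(), frame["mean_new_phams"].to_numpy(),
                   iterations, seed)


@dataclass
class ClaspResampleResult:
    """CLASP stability under subsampling of a cluster's members."""

    cluster_label: str
    sample_sizes: list[int]
    mean: dict[int, float]
    min: dict[int, float]
    max: dict[int, float]
    iterations: int
    seed: int | None


def _pham_membership(table: PhamTable, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """CSR-style (flat member indices, reduceat offsets) grouped by pham."""
    presence = table.presence[rows]
    keep = presence.any(axis=0)
    presence = presence[:, keep]
    pham_ids, genome_ids = np.nonzero(presence.T)  # row-major: grouped by pham
    counts = np.bincount(pham_ids, minlength=presence.shape[1])
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return genome_ids, offsets, presence.shape[0]


def rarefaction(table: PhamTable, iterations: int = 10_000,
                seed: int | None = None,
                genomes: list[str] | None = None) -> RarefactionResult:
    """Monte-Carlo rarefaction of pham discovery, uniform orderings.

    Each iteration draws a uniform random permutation of the genomes
    (``genomes`` restricts to a subset, e.g. one cluster) and records the
    cumulative distinct-pham count along it.  Deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    ids = list(table.genomes) if genomes is None else list(genomes)
    rows = np.array([table.genome_row(g) for g in ids])
    flat, offsets, n = _pham_membership(table, rows)
    rng = np.random.default_rng(seed)

    sums = np.zeros(n)
    sumsq = np.zeros(n)
    new_sums = np.zeros(n)
    rank = np.empty(n, dtype=np.int64)
    for _ in range(iterations):
        order = rng.permutation(n)
        rank[order] = np.arange(n)
        discovery = np.minimum.reduceat(rank[flat], offsets)
        new = np.bincount(discovery, minlength=n).astype(float)
        cum = np.cumsum(new)
        sums += cum
        sumsq += cum * cum
        new_sums += new

    mean = sums / iterations
    var = np.maximum(sumsq / iterations - mean * mean, 0.0)
    return RarefactionResult(
        n_values=np.arange(1, n + 1),
        mean_phams=mean,
        sd_phams=np.sqrt(var),
        mean_new_phams=new_sums / iterations,
        iterations=iterations,
        seed=seed,
    )


def clasp_resample(table: PhamTable, members, sizes=(5, 10, 20, 30),
                   iterations: int = 20,
                   seed: int | None = None) -> ClaspResampleResult:
    """CLASP over random member subsets of several sizes.

    Per size, ``iterations`` independent subsets are drawn uniformly
    without replacement within each subset (subsets may repeat across
    iterations) and CLASP computed on each; mean/min/max are aggregated to
    show how stable the full-cluster CLASP is under subsampling.
    """
    members = sorted(members)
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s < 2:
            raise ValueError("subset size must be >= 2 for CLASP")
        if s > len(members):
            raise ValueError(f"subset size {s} exceeds cluster size {len(members)}")
    rng = np.random.default_rng(seed)
    mean_, min_, max_ = {}, {}, {}
    for s in sizes:
        vals = []
        for _ in range(iterations):
            subset = rng.choice(len(members), size=s, replace=False)
            vals.append(clasp(table, [members[i] for i in subset]))
        mean_[s] = float(np.mean(vals))
        min_[s] = float(np.min(vals))
        max_[s] = float(np.max(vals))
    return ClaspResampleResult("", sizes, mean_, min_, max_, iterations, seed)
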