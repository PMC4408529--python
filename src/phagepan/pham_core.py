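"""Gene-content data model: gene->pham assignments and the genome x pham table.

Phage genes are grouped into protein families ("phamilies", or phams for
short); every comparative statistic downstream — shared-gene percentages,
cluster diversity indices, rarefaction curves — consumes the genome x pham
count table built here.  A pham represented by exactly one gene in the whole
dataset is an *orpham*: a gene with no detectable homologue among the
compared genomes, the footprint of recent horizontal influx.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAssignment",
    "PhamTable",
    "SharedPhamMatrix",
    "read_gene_assignments",
    "write_gene_assignments",
    "build_pham_table",
    "orphams",
    "orpham_fraction_per_genome",
    "mean_genes_per_pham",
    "pairwise_shared_percent",
    "shared_pham_matrix",
]


class PhamTableError(ValueError):
    """Raised on malformed or inconsistent gene-content input."""


@dataclass(frozen=True)
class GeneAssignment:
    """One gene of one genome, assigned to one pham."""

    genome_id: str
    gene_id: str
    pham_id: str


@dataclass
class PhamTable:
    """Genome x pham gene-count matrix.

    Parameters
    ----------
    genomes
        Ordered genome identifiers (row order of ``counts``).
    phams
        Ordered pham identifiers (column order of ``counts``).
    counts
        Integer matrix; ``counts[g, p]`` is the number of genes of pham
        ``phams[p]`` carried by genome ``genomes[g]``.
    """

    genomes: list[str]
    phams: list[str]
    counts: np.ndarray
    _genome_index: dict[str, int] = field(init=False, repr=False)
    _pham_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.genomes), len(self.phams)):
            raise PhamTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genomes)} genomes x {len(self.phams)} phams"
            )
        if (self.counts < 0).any():
            raise PhamTableError("negative gene counts")
        if len(self.phams) and (self.counts.sum(axis=0) < 1).any():
            raise PhamTableError("every pham column must contain at least one gene")
        self._genome_index = {g: i for i, g in enumerate(self.genomes)}
        self._pham_index = {p: j for j, p in enumerate(self.phams)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_phams(self) -> int:
        return len(self.phams)

    @property
    def gene_totals(self) -> np.ndarray:
        """Genes per genome (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def presence(self) -> np.ndarray:
        """Boolean genome x pham presence/absence matrix."""
        return self.counts > 0

    @property
    def total_genes(self) -> int:
        return int(self.counts.sum())

    def genome_row(self, genome_id: str) -> int:
        try:
            return self._genome_index[genome_id]
        except KeyError:
            raise PhamTableError(f"unknown genome id: {genome_id!r}") from None

    def distinct_phams(self, genome_id: str) -> set[str]:
        row = self.counts[self.genome_row(genome_id)]
        return {self.phams[j] for j in np.nonzero(row)[0]}

    def subset(self, genome_ids: list[str]) -> "PhamTable":
        """Restrict to the given genomes, dropping phams left empty."""
        rows = [self.genome_row(g) for g in genome_ids]
        sub = self.counts[rows]
        keep = sub.sum(axis=0) > 0
        return PhamTable(list(genome_ids), [p for p, k in zip(self.phams, keep) if k], sub[:, keep])

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genomes, columns=self.phams)

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        """Export the wide genome x pham count matrix as TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path) -> "PhamTable":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                   frame.to_numpy(dtype=np.int64))


@dataclass
class SharedPhamMatrix:
    """Symmetric matrix of pairwise shared-pham percentages (diagonal 100)."""

    genomes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genomes)
        if self.values.shape != (n, n):
            raise PhamTableError("shared-pham matrix must be square over the genome list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genomes, columns=self.genomes)

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().round(2).to_csv(fh, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path) -> "SharedPhamMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))


# -- assignment I/O ---------------------------------------------------------


def read_gene_assignments(path, dialect: str = "long_tsv") -> list[GeneAssignment]:
    """Read gene->pham assignments from TSV.

    ``long_tsv`` is the canonical lossless dialect: a header row
    ``genome\tgene\tpham`` followed by one row per gene.  ``pham_table_tsv``
    reads a wide genome x pham count matrix back into assignments with
    synthesised gene ids (gene identity is not recoverable from the wide
    export).
    """
    if dialect == "pham_table_tsv":
        table = PhamTable.read_tsv(path)
        out: list[GeneAssignment] = []
        for i, g in enumerate(table.genomes):
            k = 0
            for j, p in enumerate(table.phams):
                for _ in range(int(table.counts[i, j])):
                    out.append(GeneAssignment(g, f"{g}_{k}", p))
                    k += 1
        return out
    if dialect != "long_tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")

    assignments: list[GeneAssignment] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip().lower() for c in row]
                if header[:3] != ["genome", "gene", "pham"]:
                    raise PhamTableError(
                        f"line {lineno}: expected header genome/gene/pham, got {row!r}"
                    )
                continue
            if len(row) < 3 or not all(c.strip() for c in row[:3]):
                raise PhamTableError(f"line {lineno}: malformed row {row!r}")
            genome, gene, pham = (c.strip() for c in row[:3])
            if (genome, gene) in seen:
                raise PhamTableError(f"line {lineno}: duplicate gene ({genome}, {gene})")
            seen.add((genome, gene))
            assignments.append(GeneAssignment(genome, gene, pham))
    if header is None:
        raise PhamTableError("missing header row")
    return assignments


def write_gene_assignments(assignments: list[GeneAssignment], path,
                           header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("genome\tgene\tpham\n")
        for a in assignments:
            fh.write(f"{a.genome_id}\t{a.gene_id}\t{a.pham_id}\n")


def build_pham_table(assignments: list[GeneAssignment]) -> PhamTable:
    """Assemble assignments into the genome x pham count matrix.

    Genome and pham order follow first appearance in the input, so the
    table is reproducible from the same file.
    """
    if not assignments:
        raise PhamTableError("no gene assignments given")
    genomes: list[str] = []
    phams: list[str] = []
    gidx: dict[str, int] = {}
    pidx: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    triples: list[tuple[int, int]] = []
    for a in assignments:
        key = (a.genome_id, a.gene_id)
        if key in seen:
            raise PhamTableError(f"duplicate gene {key}")
        seen.add(key)
        if a.genome_id not in gidx:
            gidx[a.genome_id] = len(genomes)
            genomes.append(a.genome_id)
        if a.pham_id not in pidx:
            pidx[a.pham_id] = len(phams)
            phams.append(a.pham_id)
        triples.append((gidx[a.genome_id], pidx[a.pham_id]))
    counts = np.zeros((len(genomes), len(phams)), dtype=np.int64)
    for i, j in triples:
        counts[i, j] += 1
    return PhamTable(genomes, phams, counts)


# -- statistics -------------------------------------------------------------


def orphams(table: PhamTable) -> set[str]:
    """Phams whose total gene count across the whole dataset is exactly 1."""
    totals = table.counts.sum(axis=0)
    return {table.phams[j] for j in np.nonzero(totals == 1)[0]}


def orpham_fraction_per_genome(table: PhamTable) -> dict[str, float]:
    """Per genome, the fraction of its genes that belong to orpham phams."""
    is_orpham = table.counts.sum(axis=0) == 1
    orpham_genes = (table.counts[:, is_orpham]).sum(axis=1)
    totals = table.gene_totals
    return {
        g: (float(orpham_genes[i] / totals[i]) if totals[i] else 0.0)
        for i, g in enumerate(table.genomes)
    }


def mean_genes_per_pham(table: PhamTable) -> float:
    """Total genes divided by total phams — the mean phamily size."""
    return table.total_genes / table.n_phams


def pairwise_shared_percent(table: PhamTable, a: str, b: str) -> float:
    """Shared-pham percentage between two genomes, averaged over the pair.

    With S the number of distinct phams present in both genomes, returns
    ``100 * mean(S/|phams(a)|, S/|phams(b)|)``.  Presence/absence only:
    paralogous extra copies do not change the value.
    """
    ia, ib = table.genome_row(a), table.genome_row(b)
    pa = table.counts[ia] > 0
    pb = table.counts[ib] > 0
    shared = int(np.count_nonzero(pa & pb))
    na, nb = int(pa.sum()), int(pb.sum())
    if na == 0 or nb == 0:
        raise PhamTableError("genome with no genes has no shared-pham percentage")
    return 100.0 * 0.5 * (shared / na + shared / nb)


def shared_pham_matrix(table: PhamTable) -> SharedPhamMatrix:
    """All-pairs shared-pham percentage matrix (vectorised)."""
    presence = table.presence.astype(np.int64)
    sizes = presence.sum(axis=1).astype(float)
    if (sizes == 0).any():
        raise PhamTableError("genome with no genes in shared-pham matrix")
    overlap = presence @ presence.T
    values = 50.0 * (overlap / sizes[:, None] + overlap / sizes[None, :])
    np.fill_diagonal(values, 100.0)
    return SharedPhamMatrix(list(table.genomes), values)
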