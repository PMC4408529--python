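"""Cluster diversity and isolation indices.

Five per-cluster statistics summarise how cohesive a cluster's gene content
is and how genetically isolated it is from the rest of the population:

CLASP (CLuster Averaged Shared Phamilies)
    Mean over all unordered genome pairs of the pairwise shared-pham
    percentage (each pair's value averaged between the two partners).
    Insensitive to cluster size because pairs are averaged.
CAP (Cluster-Associated Phamilies)
    Phams present in *every* member, as a percentage of the mean number of
    distinct phams per member.
CPV (Cluster Phamily Variation)
    Percentage of the cluster's phams (union over members) that are NOT
    present in all members.  Moves inversely to CAP, imperfectly.
CCI (Cluster Cohesion Index)
    Mean genes per genome as a percentage of the cluster's total phams.
    Identical genomes with single-copy genes give exactly 100.
CII (Cluster Isolation Index)
    Percentage of the cluster's phams found in no genome outside the
    cluster; requires the table to hold the whole population.

All indices are reported on a 0-100 percent scale (``as_fraction=True``
rescales to 0-1 where a fraction convention is preferred).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .pham_core import PhamTable, PhamTableError, pairwise_shared_percent
from .sequence_compare import ClusterPartition

__all__ = ["clasp", "cap", "cpv", "cci", "cii", "cluster_report", "write_report_tsv"]


def _member_rows(table: PhamTable, members) -> list[int]:
    rows = [table.genome_row(g) for g in members]
    if not rows:
        raise PhamTableError("empty member set")
    return rows


def clasp(table: PhamTable, members) -> float:
    """Mean pairwise shared-pham percentage over all member pairs."""
    members = sorted(members)
    if len(members) < 2:
        raise PhamTableError("CLASP requires at least two genomes")
    vals = [pairwise_shared_percent(table, a, b) for a, b in combinations(members, 2)]
    return float(np.mean(vals))


def cap(table: PhamTable, members) -> float:
    """Conserved phams as a percentage of mean distinct phams per genome."""
    rows = _member_rows(table, members)
    presence = table.presence[rows]
    conserved = int(presence.all(axis=0).sum())
    mean_phams = float(presence.sum(axis=1).mean())
    if mean_phams == 0:
        raise PhamTableError("cluster members carry no genes")
    return 100.0 * conserved / mean_phams


def cpv(table: PhamTable, members) -> float:
    """Percentage of the cluster's phams not conserved in every member."""
    rows = _member_rows(table, members)
    presence = table.presence[rows]
    total = int(presence.any(axis=0).sum())
    conserved = int(presence.all(axis=0).sum())
    if total == 0:
        raise PhamTableError("cluster members carry no genes")
    return 100.0 * (total - conserved) / total


def cci(table: PhamTable, members) -> float:
    """Mean genes per genome as a percentage of the cluster's total phams."""
    rows = _member_rows(table, members)
    presence = table.presence[rows]
    total = int(presence.any(axis=0).sum())
    if total == 0:
        raise PhamTableError("cluster members carry no genes")
    mean_genes = float(table.counts[rows].sum(axis=1).mean())
    return 100.0 * mean_genes / total


def cii(table: PhamTable, members) -> float:
    """Percentage of cluster phams absent from every non-member genome."""
    rows = _member_rows(table, members)
    member_set = set(rows)
    outside = [i for i in range(table.n_genomes) if i not in member_set]
    cluster_phams = table.presence[rows].any(axis=0)
    total = int(cluster_phams.sum())
    if total == 0:
        raise PhamTableError("cluster members carry no genes")
    if not outside:
        warnings.warn("cluster spans the whole population; CII is trivially 100",
                      stacklevel=2)
        return 100.0
    outside_phams = table.presence[outside].any(axis=0)
    isolated = int((cluster_phams & ~outside_phams).sum())
    return 100.0 * isolated / total


_INDEX_COLS = ["clasp", "cap", "cpv", "cci", "cii"]


def cluster_report(table: PhamTable, partition: ClusterPartition,
                   lengths: dict[str, int] | None = None,
                   as_fraction: bool = False) -> pd.DataFrame:
    """Per-cluster summary table: sizes, gene statistics and all five indices.

    Single-genome clusters get NaN for CLASP/CAP/CCI (a pairwise or
    cohesion statistic of one genome is undefined by convention) but a
    defined CII.  ``lengths`` optionally supplies genome lengths in bp for
    a mean-length column.
    """
    missing = [g for g in table.genomes if g not in partition.assignment]
    if missing:
        raise PhamTableError(f"partition does not cover genomes: {missing[:5]}")
    rows = []
    for label, members in sorted(partition.clusters().items()):
        ridx = _member_rows(table, members)
        gene_counts = table.counts[ridx].sum(axis=1)
        presence = table.presence[ridx]
        total_phams = int(presence.any(axis=0).sum())
        single = len(members) == 1
        row = {
            "cluster": label,
            "level": partition.level,
            "n_genomes": len(members),
            "mean_genes": float(gene_counts.mean()),
            "sd_genes": float(gene_counts.std(ddof=1)) if not single else 0.0,
            "total_phams": total_phams,
            "total_genes": int(gene_counts.sum()),
            "clasp": math.nan if single else clasp(table, members),
            "cap": math.nan if single else cap(table, members),
            "cpv": cpv(table, members),
            "cci": math.nan if single else cci(table, members),
            "cii": cii(table, members),
        }
        if lengths is not None:
            row["mean_length"] = float(np.mean([lengths[g] for g in members]))
        rows.append(row)
    report = pd.DataFrame(rows).set_index("cluster")
    if as_fraction:
        report[_INDEX_COLS] = report[_INDEX_COLS] / 100.0
    return report


def write_report_tsv(report: pd.DataFrame, path,
                     header_comment: str | None = None) -> None:
    """Write the cluster report as TSV; undefined index cells print N/A."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        report.to_csv(fh, sep="\t", na_rep="N/A", float_format="%.2f")
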