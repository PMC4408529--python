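"""Word-match dotplots, similarity spans, and nucleotide-based clustering.

Phage genomes are grouped into clusters when evident DNA similarity spans
more than half of the genome lengths.  This module approximates that rule
without a full aligner: shared exact words of length ``w`` (default 10, the
conventional dotplot word length) are projected onto each genome, merged
into similarity segments, and the covered fraction of each genome's length
is thresholded to build a cluster graph whose connected components are the
clusters.  Cluster relations are genuinely intransitive in real data — a
genome can bridge two otherwise-distant groups — so connected components
(single linkage) are the only input-order-independent automation; curated
clusters can differ.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "DotplotMatches",
    "SimilaritySpanMatrix",
    "ClusterPartition",
    "read_fasta",
    "write_fasta",
    "dotplot",
    "span_fraction",
    "similarity_span_matrix",
    "assign_clusters",
    "assign_subclusters",
    "cluster_labels",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class SequenceError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A genome's DNA sequence over {A,C,G,T}, uppercased on construction."""

    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID
        if bad:
            raise SequenceError(f"{self.genome_id}: non-ACGT characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DotplotMatches:
    """Exact word matches between two sequences.

    ``pairs`` holds ``(posA, posB, strand)`` with 0-based positions; a
    reverse-strand pair means the word at posA on A equals the reverse
    complement of the word at posB on B, both positions given in forward
    coordinates.
    """

    word_length: int
    pairs: set[tuple[int, int, str]]

    def positions_a(self) -> list[int]:
        return sorted({p[0] for p in self.pairs})

    def positions_b(self) -> list[int]:
        return sorted({p[1] for p in self.pairs})

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("posA\tposB\tstrand\n")
            for pa, pb, s in sorted(self.pairs):
                fh.write(f"{pa}\t{pb}\t{s}\n")


@dataclass
class SimilaritySpanMatrix:
    """Per ordered pair (a, b): fraction of a's length covered by merged
    similarity segments to b.  Asymmetric by construction (each row is
    normalised by the row genome's length); diagonal is 1."""

    genomes: list[str]
    span_frac: np.ndarray

    def __post_init__(self) -> None:
        self.span_frac = np.asarray(self.span_frac, dtype=float)
        n = len(self.genomes)
        if self.span_frac.shape != (n, n):
            raise SequenceError("span matrix must be square over the genome list")
        if ((self.span_frac < 0) | (self.span_frac > 1)).any():
            raise SequenceError("span fractions must lie in [0, 1]")

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        import pandas as pd

        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            pd.DataFrame(self.span_frac, index=self.genomes,
                         columns=self.genomes).to_csv(fh, sep="\t", index_label="genome")

    @classmethod
    def read_tsv(cls, path) -> "SimilaritySpanMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))


@dataclass
class ClusterPartition:
    """Assignment of every genome to exactly one cluster label."""

    assignment: dict[str, str]
    singletons: set[str] = field(default_factory=set)
    level: str = "cluster"

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, label in self.assignment.items():
            out.setdefault(label, []).append(g)
        for members in out.values():
            members.sort()
        return out

    def members_of(self, label: str) -> list[str]:
        return self.clusters()[label]

    @property
    def labels(self) -> list[str]:
        return sorted(self.clusters())


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> list[GenomeSequence]:
    return [GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: list[GenomeSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.genome_id}\n")
            for i in range(0, len(s.sequence), 70):
                fh.write(s.sequence[i:i + 70] + "\n")


# -- dotplots and spans -----------------------------------------------------


def dotplot(a: GenomeSequence, b: GenomeSequence, w: int = 10) -> DotplotMatches:
    """All shared w-mer occurrence pairs between two genomes, both strands."""
    if w < 4:
        raise SequenceError("word length must be >= 4")
    if len(a) < w or len(b) < w:
        raise SequenceError("sequence shorter than the word length")

    fwd: dict[str, list[int]] = {}
    rev: dict[str, list[int]] = {}
    sb = b.sequence
    for j in range(len(sb) - w + 1):
        word = sb[j:j + w]
        fwd.setdefault(word, []).append(j)
        rev.setdefault(revcomp(word), []).append(j)

    pairs: set[tuple[int, int, str]] = set()
    sa = a.sequence
    for i in range(len(sa) - w + 1):
        word = sa[i:i + w]
        for j in fwd.get(word, ()):
            pairs.add((i, j, "fwd"))
        for j in rev.get(word, ()):
            pairs.add((i, j, "rev"))
    return DotplotMatches(w, pairs)


def _merged_coverage(starts: list[int], w: int, merge_gap: int, length: int) -> int:
    """Union length of [s, s+w) intervals after bridging gaps <= merge_gap."""
    if not starts:
        return 0
    covered = 0
    lo = starts[0]
    hi = starts[0] + w
    for s in starts[1:]:
        if s <= hi + merge_gap:
            hi = max(hi, s + w)
        else:
            covered += hi - lo
            lo, hi = s, s + w
    covered += hi - lo
    return min(covered, length)


def span_fraction(a: GenomeSequence, b: GenomeSequence, w: int = 10,
                  merge_gap: int | None = None) -> tuple[float, float]:
    """Fraction of each genome's length covered by similarity to the other.

    Word matches are widened to w-length intervals, merged when separated
    by at most ``merge_gap`` (default 3*w, enough to bridge point
    mutations without inventing an aligner), and the union length is
    divided by the genome length.
    """
    if merge_gap is None:
        merge_gap = 3 * w
    matches = dotplot(a, b, w)
    cov_a = _merged_coverage(matches.positions_a(), w, merge_gap, len(a))
    cov_b = _merged_coverage(matches.positions_b(), w, merge_gap, len(b))
    return cov_a / len(a), cov_b / len(b)


def similarity_span_matrix(seqs: list[GenomeSequence], w: int = 10,
                           merge_gap: int | None = None) -> SimilaritySpanMatrix:
    ids = [s.genome_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate genome ids")
    n = len(seqs)
    frac = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            fa, fb = span_fraction(seqs[i], seqs[j], w, merge_gap)
            frac[i, j] = fa
            frac[j, i] = fb
    return SimilaritySpanMatrix(ids, frac)


# -- clustering -------------------------------------------------------------


def cluster_labels() -> "itertools.chain":
    """A, B, ..., Z, AA, AB, ... — stable label sequence for clusters."""
    singles = iter(string.ascii_uppercase)
    doubles = ("".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2))
    return itertools.chain(singles, doubles)


def _components_partition(genomes: list[str], edges: list[tuple[str, str]],
                          label_of, level: str) -> ClusterPartition:
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    graph.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    # deterministic: descending size, ties by lexicographically smallest member
    comps.sort(key=lambda c: (-len(c), c[0]))
    assignment: dict[str, str] = {}
    singletons: set[str] = set()
    for comp, label in zip(comps, label_of):
        for g in comp:
            assignment[g] = label
        if len(comp) == 1:
            singletons.add(label)
    return ClusterPartition(assignment, singletons, level=level)


def assign_clusters(spans: SimilaritySpanMatrix, threshold: float = 0.5,
                    rule: str = "both") -> ClusterPartition:
    """Cluster genomes by the >threshold similarity-span rule.

    An edge joins (a, b) when the span fraction exceeds ``threshold`` on
    both genomes (``rule='both'``, default — "genome lengths" plural) or on
    either (``rule='either'``).  Clusters are connected components, labelled
    A, B, C, ... by descending size; size-1 components are singletons.
    """
    if rule not in ("both", "either"):
        raise ValueError(f"rule must be 'both' or 'either', got {rule!r}")
    frac = spans.span_frac
    n = len(spans.genomes)
    if not np.allclose(np.diag(frac), 1.0):
        raise SequenceError("span matrix diagonal must be 1")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = frac[i, j] > threshold, frac[j, i] > threshold
            if (a and b) if rule == "both" else (a or b):
                edges.append((spans.genomes[i], spans.genomes[j]))
    return _components_partition(list(spans.genomes), edges, cluster_labels(), "cluster")


def assign_subclusters(members: list[str], spans: SimilaritySpanMatrix,
                       sub_threshold: float, cluster_label: str = "A",
                       primary_threshold: float = 0.5,
                       rule: str = "both") -> ClusterPartition:
    """Split one cluster into subclusters at a stricter span threshold.

    Subcluster membership criteria are not standardised; here a subcluster
    is a connected component of the same span graph evaluated at
    ``sub_threshold`` (> the primary threshold), labelled A1, A2, ... by
    descending size.
    """
    if sub_threshold <= primary_threshold:
        raise ValueError("sub_threshold must exceed the primary cluster threshold")
    index = {g: i for i, g in enumerate(spans.genomes)}
    missing = [g for g in members if g not in index]
    if missing:
        raise SequenceError(f"genomes not in span matrix: {missing}")
    frac = spans.span_frac
    edges = []
    ms = sorted(members)
    for x in range(len(ms)):
        for y in range(x + 1, len(ms)):
            i, j = index[ms[x]], index[ms[y]]
            a, b = frac[i, j] > sub_threshold, frac[j, i] > sub_threshold
            if (a and b) if rule == "both" else (a or b):
                edges.append((ms[x], ms[y]))
    labels = (f"{cluster_label}{k}" for k in itertools.count(1))
    return _components_partition(ms, edges, labels, "subcluster")
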