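"""Synthetic phage populations with clustered gene content and gene influx.

The generator emulates the statistical structure of a clustered phage
collection: every genome belongs to a cluster, carries all of its
cluster's core phams, a Bernoulli sample of the cluster's accessory pool,
an optional Bernoulli sample of a population-wide shared pool
(cross-cluster sharing), and a Poisson number of brand-new single-copy
phams drawn from an effectively infinite outside pool — the horizontal
gene-influx term.  Influx phams are never reused, so every one is an
orpham by construction and the expected new-pham increment of a
rarefaction curve converges to the configured influx rate.

Optional toy nucleotide sequences assign each pham one canonical random
segment; a genome's sequence is the concatenation of its phams' canonical
segments (pham-sorted, each copy independently point-mutated), so genomes
sharing phams share near-identical spans and the similarity-span
clustering can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .pham_core import GeneAssignment
from .sequence_compare import GenomeSequence

__all__ = [
    "ClusterConfig",
    "SequenceOpts",
    "PopulationConfig",
    "SyntheticPopulation",
    "generate_population",
    "generate_sequences",
    "table1_like",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


@dataclass
class ClusterConfig:
    """One cluster's gene-content regime.

    mean_extra_genes is the expected (Poisson) number of paralogous
    duplicate genes per genome, assigned to phams the genome already
    carries; 0 keeps the one-gene-per-pham default.
    """

    label: str
    n_genomes: int
    core_phams: int
    accessory_pool: int = 0
    accessory_prob: float = 0.5
    mean_extra_genes: float = 0.0

    def validate(self) -> None:
        if self.n_genomes < 1 or self.core_phams < 0 or self.accessory_pool < 0:
            raise ConfigError(f"cluster {self.label}: counts must be non-negative")
        if not 0.0 <= self.accessory_prob <= 1.0:
            raise ConfigError(f"cluster {self.label}: accessory_prob outside [0, 1]")
        if self.mean_extra_genes < 0:
            raise ConfigError(f"cluster {self.label}: mean_extra_genes must be >= 0")
        if self.core_phams + self.accessory_pool == 0:
            raise ConfigError(f"cluster {self.label}: no phams to draw from")


@dataclass
class SequenceOpts:
    """Toy sequence synthesis: per-pham segment length and copy mutation rate."""

    pham_length_mean: float = 300.0
    pham_length_sd: float = 50.0
    mutation_rate: float = 0.0

    def validate(self, word_length: int = 10) -> None:
        if self.pham_length_mean < 3 * word_length:
            raise ConfigError("pham_length_mean must be at least 3x the dotplot word length")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate outside [0, 1]")


@dataclass
class PopulationConfig:
    clusters: list[ClusterConfig]
    global_pool: int = 0
    global_prob: float = 0.0
    influx_rate: float = 0.0
    seed: int = 0
    sequence_opts: SequenceOpts | None = None

    def validate(self) -> None:
        if not self.clusters:
            raise ConfigError("at least one cluster is required")
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate cluster labels")
        for c in self.clusters:
            c.validate()
        if self.global_pool < 0 or not 0.0 <= self.global_prob <= 1.0:
            raise ConfigError("invalid global pool settings")
        if self.influx_rate < 0:
            raise ConfigError("influx_rate must be >= 0")
        if self.sequence_opts is not None:
            self.sequence_opts.validate()

    # -- config file round trip --------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        clusters = [ClusterConfig(**c) for c in raw.pop("clusters")]
        seq = raw.pop("sequence_opts", None)
        opts = SequenceOpts(**seq) if seq else None
        return cls(clusters=clusters, sequence_opts=opts, **raw)


@dataclass
class SyntheticPopulation:
    assignments: list[GeneAssignment]
    truth: dict = field(default_factory=dict)
    config: PopulationConfig | None = None


def generate_population(config: PopulationConfig) -> SyntheticPopulation:
    """Draw a clustered gene-content population; deterministic given seed.

    Per genome: all cluster core phams, Bernoulli(accessory_prob) draws
    from the cluster accessory pool, Bernoulli(global_prob) draws from the
    shared global pool, Poisson(influx_rate) globally-unique novel phams,
    and Poisson(mean_extra_genes) paralogous duplicates.  One gene per
    included pham otherwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    assignments: list[GeneAssignment] = []
    cluster_of: dict[str, str] = {}
    influx_counter = 0

    for cl in config.clusters:
        core = [f"{cl.label}_core{i}" for i in range(cl.core_phams)]
        acc = [f"{cl.label}_acc{i}" for i in range(cl.accessory_pool)]
        for k in range(cl.n_genomes):
            genome = f"{cl.label}{k + 1:03d}"
            cluster_of[genome] = cl.label
            phams = list(core)
            if acc:
                take = rng.random(len(acc)) < cl.accessory_prob
                phams.extend(p for p, t in zip(acc, take) if t)
            if config.global_pool:
                take = rng.random(config.global_pool) < config.global_prob
                phams.extend(f"GLOB{i}" for i in np.nonzero(take)[0])
            n_novel = rng.poisson(config.influx_rate)
            for _ in range(n_novel):
                phams.append(f"NOV{influx_counter}")
                influx_counter += 1
            if cl.mean_extra_genes > 0 and phams:
                n_extra = rng.poisson(cl.mean_extra_genes)
                phams.extend(rng.choice(phams, size=n_extra, replace=True).tolist())
            for g_i, pham in enumerate(phams):
                assignments.append(GeneAssignment(genome, f"gene{g_i:04d}", pham))

    truth = {
        "cluster_of": cluster_of,
        "influx_rate": config.influx_rate,
        "n_influx_phams": influx_counter,
        "seed": config.seed,
    }
    return SyntheticPopulation(assignments, truth, config)


def _random_segment(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        arr[hits] = rng.choice(_BASES, size=len(hits))
    return arr.tobytes().decode("ascii")


def generate_sequences(pop: SyntheticPopulation,
                       config: PopulationConfig | None = None) -> list[GenomeSequence]:
    """Toy genome sequences consistent with the population's gene content.

    Each pham gets one canonical random segment (length ~ Normal(mean, sd),
    floored at 3x a word length of 10); a genome is the concatenation of
    its phams' canonicals in sorted pham order, every copy independently
    mutated at the configured per-base rate.
    """
    config = config or pop.config
    if config is None or config.sequence_opts is None:
        raise ConfigError("sequence_opts required to generate sequences")
    opts = config.sequence_opts
    opts.validate()
    # child stream so sequences do not perturb the gene-content draws
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 94]))

    genome_phams: dict[str, list[str]] = {}
    all_phams: set[str] = set()
    for a in pop.assignments:
        genome_phams.setdefault(a.genome_id, []).append(a.pham_id)
        all_phams.add(a.pham_id)

    min_len = 30
    canonical: dict[str, str] = {}
    for pham in sorted(all_phams):
        length = max(min_len, int(round(rng.normal(opts.pham_length_mean,
                                                   opts.pham_length_sd))))
        canonical[pham] = _random_segment(rng, length)

    out = []
    for genome in sorted(genome_phams):
        parts = [_mutate(rng, canonical[p], opts.mutation_rate)
                 for p in sorted(genome_phams[genome])]
        out.append(GenomeSequence(genome, "".join(parts)))
    return out


# Table-1-like preset: the 20 cluster sizes and per-genome gene means of the
# 627-phage collection (A:232 genomes/90 genes ... T:3/67) plus 8 singletons
# dominated by novel genes.
_TABLE1_SIZES = {
    "A": (232, 90), "B": (109, 100), "C": (45, 231), "D": (10, 89),
    "E": (35, 142), "F": (66, 105), "G": (14, 62), "H": (5, 98),
    "I": (4, 78), "J": (16, 240), "K": (32, 96), "L": (13, 128),
    "M": (3, 141), "N": (7, 69), "O": (5, 124), "P": (9, 79),
    "Q": (5, 85), "R": (4, 102), "S": (2, 109), "T": (3, 67),
}
_SINGLETON_GENES = 95


def table1_like(seed: int = 0, influx_rate: float = 2.5,
                size_scale: float = 1.0,
                sequence_opts: SequenceOpts | None = None) -> PopulationConfig:
    """Preset emulating a large clustered collection: 20 clusters with
    sizes spanning 2-232 genomes, 8 singletons rich in novel genes, a
    shared global pool, and a constant influx of ~2.5 novel phams per
    genome.  ``size_scale`` shrinks cluster sizes proportionally (minimum
    2) for desk-scale runs."""
    clusters = []
    for label, (n, genes) in _TABLE1_SIZES.items():
        n_scaled = max(2, int(round(n * size_scale)))
        clusters.append(ClusterConfig(
            label=label,
            n_genomes=n_scaled,
            core_phams=max(1, int(round(0.4 * genes))),
            accessory_pool=int(round(1.2 * genes)),
            accessory_prob=0.5,
        ))
    # singletons: clusters of one whose private "core" genes are all orphams
    for i in range(8):
        clusters.append(ClusterConfig(
            label=f"sing{i + 1}",
            n_genomes=1,
            core_phams=int(round(0.6 * _SINGLETON_GENES)),
            accessory_pool=0,
            accessory_prob=0.0,
        ))
    return PopulationConfig(
        clusters=clusters,
        global_pool=300,
        global_prob=0.1,
        influx_rate=influx_rate,
        seed=seed,
        sequence_opts=sequence_opts,
    )
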