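"""The synthetic population generator: configured regimes show up in the data."""

import numpy as np
import pytest

from phagepan import (
    ClusterConfig,
    PopulationConfig,
    SequenceOpts,
    assign_clusters,
    build_pham_table,
    cap,
    cii,
    clasp,
    cci,
    generate_population,
    generate_sequences,
    orphams,
    similarity_span_matrix,
    span_fraction,
    table1_like,
)
from phagepan.synthetic_data import ConfigError

from conftest import make_table  # noqa: F401  (shared helpers live here)


def truth_partition(pop):
    inv = {}
    for g, c in pop.truth["cluster_of"].items():
        inv.setdefault(c, set()).add(g)
    return {frozenset(v) for v in inv.values()}


class TestGeneratePopulation:
    def test_degenerate_config_gives_identical_members(self):
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 5, 20, 10, accessory_prob=1.0)],
            influx_rate=0.0, seed=1)
        table = build_pham_table(generate_population(cfg).assignments)
        members = list(table.genomes)
        assert clasp(table, members) == 100.0
        assert cap(table, members) == 100.0
        assert cci(table, members) == 100.0

    def test_binomial_accessory_expectations(self):
        """core=50 + accessory 100 @ p=0.5: expected distinct phams per
        genome is 100 and CAP heads toward 50/100."""
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 40, 50, 100, accessory_prob=0.5)],
            influx_rate=0.0, seed=2)
        table = build_pham_table(generate_population(cfg).assignments)
        per_genome = table.presence.sum(axis=1)
        # mean 100, sd 5 per genome; sample-mean sd ~ 5/sqrt(40)
        assert per_genome.mean() == pytest.approx(100.0, abs=3.0)
        # with 40 members every accessory pham is almost surely missing
        # somewhere, so conserved ~= core and CAP ~= 100*50/100
        assert cap(table, list(table.genomes)) == pytest.approx(50.0, abs=3.0)

    def test_influx_phams_are_unique_orphams(self):
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 30, 10, 0, 0.0)], influx_rate=3.0, seed=3)
        pop = generate_population(cfg)
        table = build_pham_table(pop.assignments)
        novel = {p for p in table.phams if p.startswith("NOV")}
        assert novel <= orphams(table)
        assert len(novel) == pop.truth["n_influx_phams"]
        # Poisson(3) over 30 genomes: total within ~4 sd of 90
        assert len(novel) == pytest.approx(90, abs=4 * np.sqrt(90))

    def test_influx_rate_matches_rarefaction_tail(self):
        from phagepan import estimate_c_phage, rarefaction
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 300, 50, 100, 0.5)], influx_rate=2.5, seed=4)
        table = build_pham_table(generate_population(cfg).assignments)
        res = rarefaction(table, iterations=300, seed=5)
        assert estimate_c_phage(res) == pytest.approx(2.5, abs=0.5)

    def test_deterministic_given_seed(self):
        cfg = lambda: PopulationConfig(  # noqa: E731
            clusters=[ClusterConfig("A", 10, 5, 10, 0.5)], influx_rate=1.0, seed=42)
        a = generate_population(cfg()).assignments
        b = generate_population(cfg()).assignments
        assert a == b

    def test_disjoint_pools_isolate_shared_pool_links(self):
        base = dict(clusters=[ClusterConfig("A", 5, 20, 0, 0.0),
                              ClusterConfig("B", 5, 20, 0, 0.0)],
                    influx_rate=0.0, seed=6)
        isolated = build_pham_table(
            generate_population(PopulationConfig(**base)).assignments)
        shared = build_pham_table(
            generate_population(
                PopulationConfig(**base, global_pool=50, global_prob=0.8)).assignments)
        a_members = [g for g in isolated.genomes if g.startswith("A")]
        assert cii(isolated, a_members) == 100.0
        a_members2 = [g for g in shared.genomes if g.startswith("A")]
        assert cii(shared, a_members2) < 100.0

    def test_paralogs_only_when_requested(self):
        no_paralogs = PopulationConfig(
            clusters=[ClusterConfig("A", 10, 20, 0, 0.0)], seed=7)
        t1 = build_pham_table(generate_population(no_paralogs).assignments)
        assert t1.counts.max() == 1
        with_paralogs = PopulationConfig(
            clusters=[ClusterConfig("A", 10, 20, 0, 0.0, mean_extra_genes=3.0)], seed=7)
        t2 = build_pham_table(generate_population(with_paralogs).assignments)
        assert t2.counts.max() > 1

    @pytest.mark.parametrize("bad", [
        dict(clusters=[]),
        dict(clusters=[ClusterConfig("A", 0, 5)]),
        dict(clusters=[ClusterConfig("A", 2, 5, accessory_prob=1.5)]),
        dict(clusters=[ClusterConfig("A", 2, 5)], influx_rate=-1.0),
        dict(clusters=[ClusterConfig("A", 2, 5), ClusterConfig("A", 2, 5)]),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            generate_population(PopulationConfig(**bad))

    def test_yaml_round_trip(self, tmp_path):
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 4, 10, 5, 0.3)],
            global_pool=20, global_prob=0.1, influx_rate=1.5, seed=9,
            sequence_opts=SequenceOpts(200, 30, 0.01))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PopulationConfig.from_yaml(path) == cfg


class TestGenerateSequences:
    def test_identical_pham_sets_give_identical_sequences(self):
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 2, 8, 0, 0.0)], seed=10,
            sequence_opts=SequenceOpts(120, 20, mutation_rate=0.0))
        pop = generate_population(cfg)
        s1, s2 = generate_sequences(pop)
        assert s1.sequence == s2.sequence
        assert span_fraction(s1, s2, 10) == (1.0, 1.0)

    def test_half_shared_content_gives_half_span(self):
        """Two genomes sharing half their pham-length: span fractions near 0.5."""
        from phagepan import GeneAssignment
        from phagepan.synthetic_data import SyntheticPopulation
        shared = [f"S{i}" for i in range(6)]
        assignments = (
            [GeneAssignment("g1", f"a{i}", p) for i, p in enumerate(shared + [f"X{i}" for i in range(6)])]
            + [GeneAssignment("g2", f"b{i}", p) for i, p in enumerate(shared + [f"Y{i}" for i in range(6)])]
        )
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 1, 1)], seed=11,
            sequence_opts=SequenceOpts(200, 0.0, mutation_rate=0.0))
        pop = SyntheticPopulation(assignments, {}, cfg)
        s1, s2 = generate_sequences(pop)
        fa, fb = span_fraction(s1, s2, 10)
        assert fa == pytest.approx(0.5, abs=0.05)
        assert fb == pytest.approx(0.5, abs=0.05)

    def test_disjoint_content_gives_zero_span(self):
        cfg = PopulationConfig(
            clusters=[ClusterConfig("A", 1, 10), ClusterConfig("B", 1, 10)],
            seed=12, sequence_opts=SequenceOpts(150, 25, mutation_rate=0.0))
        pop = generate_population(cfg)
        s1, s2 = generate_sequences(pop)
        fa, fb = span_fraction(s1, s2, 10)
        # chance 10-mer collisions between ~1.5 kb random sequences leave a
        # few spurious matches; spans stay far below the 0.5 cluster rule
        assert fa < 0.1 and fb < 0.1

    def test_missing_sequence_opts_rejected(self):
        cfg = PopulationConfig(clusters=[ClusterConfig("A", 2, 5)], seed=13)
        pop = generate_population(cfg)
        with pytest.raises(ConfigError):
            generate_sequences(pop)

    def test_cluster_recovery_from_sequences(self):
        """Mutation-free sequences from a 3-cluster config: the span-rule
        partition equals the generator's ground truth exactly."""
        cfg = PopulationConfig(
            clusters=[ClusterConfig(l, 4, 10, 4, 0.5) for l in "XYZ"],
            seed=14, sequence_opts=SequenceOpts(250, 40, mutation_rate=0.0))
        pop = generate_population(cfg)
        spans = similarity_span_matrix(generate_sequences(pop))
        part = assign_clusters(spans)
        got = {frozenset(v) for v in part.clusters().values()}
        assert got == truth_partition(pop)


class TestTable1Preset:
    def test_preset_shape(self):
        cfg = table1_like(seed=0)
        sizes = sorted(c.n_genomes for c in cfg.clusters)
        assert len(cfg.clusters) == 28  # 20 clusters + 8 singletons
        assert max(sizes) == 232 and sizes.count(1) == 8
        assert cfg.influx_rate == 2.5

    def test_scaled_preset_generates_plausible_population(self):
        cfg = table1_like(seed=1, size_scale=0.05)
        pop = generate_population(cfg)
        table = build_pham_table(pop.assignments)
        genes = table.gene_totals
        # per-genome gene counts in the tens-to-hundreds range
        assert 20 <= genes.min() and genes.max() <= 400
        # singletons are mostly orphams (their private genes have no homologues)
        from phagepan import orpham_fraction_per_genome
        fracs = orpham_fraction_per_genome(table)
        singleton_ids = [g for g, c in pop.truth["cluster_of"].items()
                         if c.startswith("sing")]
        assert all(fracs[g] > 0.30 for g in singleton_ids)
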