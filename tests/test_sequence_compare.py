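"""Dotplots, similarity spans and span-threshold clustering vs brute-force oracles."""

import itertools

import numpy as np
import pytest

from phagepan import (
    GenomeSequence,
    SimilaritySpanMatrix,
    assign_clusters,
    assign_subclusters,
    dotplot,
    read_fasta,
    span_fraction,
    similarity_span_matrix,
)
from phagepan.sequence_compare import SequenceError, revcomp, write_fasta


def brute_force_dotplot(a: str, b: str, w: int):
    """Independent oracle: all-pairs w-mer comparison, both strands."""
    pairs = set()
    for i in range(len(a) - w + 1):
        wa = a[i:i + w]
        for j in range(len(b) - w + 1):
            wb = b[j:j + w]
            if wa == wb:
                pairs.add((i, j, "fwd"))
            if wa == revcomp(wb):
                pairs.add((i, j, "rev"))
    return pairs


def brute_force_coverage(starts, w, gap, length):
    """Oracle: mark every base of each widened interval, bridging gaps."""
    covered = np.zeros(length, bool)
    for s in starts:
        covered[s:s + w] = True
    # bridge runs of uncovered bases of length <= gap between covered runs
    idx = np.flatnonzero(covered)
    if len(idx) == 0:
        return 0
    out = covered.copy()
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= gap + 1:
            out[a:b] = True
    return int(out.sum())


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDotplot:
    def test_self_dotplot_contains_diagonal(self):
        a = GenomeSequence("a", "ACGTACGTACGT")
        m = dotplot(a, a, 4)
        for i in range(len(a) - 3):
            assert (i, i, "fwd") in m.pairs

    def test_reverse_complement_only_matches(self):
        a = GenomeSequence("a", "AAAACCCC")
        b = GenomeSequence("b", "GGGGTTTT")
        m = dotplot(a, b, 4)
        assert all(s == "rev" for _, _, s in m.pairs)
        # e.g. AAAA at a:0 is the revcomp of TTTT at b:4
        assert (0, 4, "rev") in m.pairs
        assert m.pairs == brute_force_dotplot(a.sequence, b.sequence, 4)

    def test_random_unrelated_sequences_share_nothing(self):
        rng = np.random.default_rng(11)
        a = GenomeSequence("a", random_seq(rng, 200))
        b = GenomeSequence("b", random_seq(rng, 200))
        assert dotplot(a, b, 10).pairs == set()

    @pytest.mark.parametrize("seed,la,lb,w", [(0, 120, 150, 4), (1, 300, 200, 6),
                                              (2, 80, 80, 5)])
    def test_matches_brute_force_oracle(self, seed, la, lb, w):
        rng = np.random.default_rng(seed)
        # embed a shared segment so matches exist
        shared = random_seq(rng, 40)
        a = GenomeSequence("a", random_seq(rng, la) + shared)
        b = GenomeSequence("b", shared + random_seq(rng, lb))
        assert dotplot(a, b, w).pairs == brute_force_dotplot(a.sequence, b.sequence, w)

    def test_too_short_sequence_errors(self):
        with pytest.raises(SequenceError):
            dotplot(GenomeSequence("a", "ACG"), GenomeSequence("b", "ACGTACGT"), 4)

    def test_small_word_length_rejected(self):
        a = GenomeSequence("a", "ACGTACGT")
        with pytest.raises(SequenceError):
            dotplot(a, a, 3)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(SequenceError):
            GenomeSequence("a", "ACGTN")


class TestSpanFraction:
    def test_identical_sequences_cover_fully(self):
        rng = np.random.default_rng(5)
        a = GenomeSequence("a", random_seq(rng, 500))
        assert span_fraction(a, a, 10) == (1.0, 1.0)

    def test_half_genome_containment(self):
        rng = np.random.default_rng(8)
        full = random_seq(rng, 1000)
        a = GenomeSequence("a", full)
        b = GenomeSequence("b", full[:500])
        fa, fb = span_fraction(a, b, 10, merge_gap=0)
        assert fa == pytest.approx(0.5, abs=0.02)
        assert fb == pytest.approx(1.0, abs=0.02)

    def test_unrelated_sequences_give_zero(self):
        rng = np.random.default_rng(9)
        a = GenomeSequence("a", random_seq(rng, 300))
        b = GenomeSequence("b", random_seq(rng, 300))
        assert span_fraction(a, b, 10) == (0.0, 0.0)

    @pytest.mark.parametrize("gap", [0, 5, 30])
    def test_coverage_matches_interval_oracle(self, gap):
        rng = np.random.default_rng(13)
        shared1, shared2 = random_seq(rng, 60), random_seq(rng, 45)
        a = GenomeSequence("a", shared1 + random_seq(rng, 200) + shared2)
        b = GenomeSequence("b", random_seq(rng, 100) + shared1 + shared2)
        w = 10
        m = dotplot(a, b, w)
        fa, fb = span_fraction(a, b, w, merge_gap=gap)
        assert fa * len(a) == pytest.approx(
            brute_force_coverage(m.positions_a(), w, gap, len(a)))
        assert fb * len(b) == pytest.approx(
            brute_force_coverage(m.positions_b(), w, gap, len(b)))

    def test_coverage_monotone_in_merge_gap_and_bounded(self):
        rng = np.random.default_rng(21)
        shared = random_seq(rng, 50)
        a = GenomeSequence("a", shared + random_seq(rng, 150) + shared)
        b = GenomeSequence("b", shared)
        fracs = [span_fraction(a, b, 10, merge_gap=g)[0] for g in (0, 10, 50, 400)]
        assert all(0.0 <= f <= 1.0 for f in fracs)
        assert fracs == sorted(fracs)


def spans_from(ids, pairs):
    """Build a span matrix from {(a, b): (frac_ab, frac_ba)}; rest 0."""
    n = len(ids)
    frac = np.eye(n)
    index = {g: i for i, g in enumerate(ids)}
    for (a, b), (fab, fba) in pairs.items():
        frac[index[a], index[b]] = fab
        frac[index[b], index[a]] = fba
    return SimilaritySpanMatrix(list(ids), frac)


class TestAssignClusters:
    def test_all_similar_forms_one_cluster(self):
        spans = spans_from("abc", {("a", "b"): (1, 1), ("a", "c"): (1, 1),
                                   ("b", "c"): (1, 1)})
        part = assign_clusters(spans)
        assert set(part.assignment.values()) == {"A"}
        assert part.singletons == set()

    def test_transitive_chain_is_one_cluster(self):
        # a-b and b-c above threshold, a-c far below: single linkage joins all
        spans = spans_from("abc", {("a", "b"): (0.6, 0.6), ("b", "c"): (0.6, 0.6),
                                   ("a", "c"): (0.1, 0.1)})
        part = assign_clusters(spans)
        assert len(set(part.assignment.values())) == 1

    def test_all_dissimilar_are_singletons(self):
        spans = spans_from("abc", {("a", "b"): (0.2, 0.2), ("a", "c"): (0.2, 0.2),
                                   ("b", "c"): (0.2, 0.2)})
        part = assign_clusters(spans)
        assert len(set(part.assignment.values())) == 3
        assert len(part.singletons) == 3

    def test_both_rule_requires_both_directions(self):
        spans = spans_from("ab", {("a", "b"): (0.8, 0.3)})
        assert len(set(assign_clusters(spans, rule="both").assignment.values())) == 2
        assert len(set(assign_clusters(spans, rule="either").assignment.values())) == 1

    def test_labels_by_descending_size_then_member_id(self):
        spans = spans_from("abcde", {("d", "e"): (0.9, 0.9), ("a", "b"): (0.9, 0.9),
                                     ("b", "c"): (0.9, 0.9)})
        part = assign_clusters(spans)
        assert part.assignment["a"] == "A"          # size-3 cluster first
        assert part.assignment["d"] == "B"
        assert part.members_of("A") == ["a", "b", "c"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(6)]
        pairs = {("g0", "g1"): (0.7, 0.7), ("g2", "g3"): (0.8, 0.8),
                 ("g3", "g4"): (0.8, 0.8)}
        base = assign_clusters(spans_from(ids, pairs))
        for _ in range(5):
            perm = list(rng.permutation(ids))
            frac = spans_from(ids, pairs).span_frac
            order = [ids.index(g) for g in perm]
            shuffled = SimilaritySpanMatrix(perm, frac[np.ix_(order, order)])
            assert assign_clusters(shuffled).assignment == base.assignment

    def test_bad_diagonal_rejected(self):
        mat = SimilaritySpanMatrix(["a", "b"], np.array([[0.5, 0.2], [0.2, 1.0]]))
        with pytest.raises(SequenceError):
            assign_clusters(mat)


class TestSubclusters:
    def test_uniformly_tight_cluster_is_one_subcluster(self):
        spans = spans_from("abc", {("a", "b"): (0.95, 0.95), ("a", "c"): (0.95, 0.95),
                                   ("b", "c"): (0.95, 0.95)})
        part = assign_subclusters(["a", "b", "c"], spans, 0.8, "A")
        assert set(part.assignment.values()) == {"A1"}

    def test_two_blocks_split_at_stricter_threshold(self):
        spans = spans_from("abcd", {("a", "b"): (0.95, 0.95), ("c", "d"): (0.95, 0.95),
                                    ("a", "c"): (0.6, 0.6), ("b", "d"): (0.6, 0.6),
                                    ("a", "d"): (0.6, 0.6), ("b", "c"): (0.6, 0.6)})
        part = assign_subclusters(list("abcd"), spans, 0.8, "A")
        assert len(set(part.assignment.values())) == 2
        assert part.assignment["a"] == part.assignment["b"]
        assert part.assignment["c"] == part.assignment["d"]

    def test_single_member_is_its_own_subcluster(self):
        spans = spans_from("a", {})
        part = assign_subclusters(["a"], spans, 0.8, "Q")
        assert part.assignment == {"a": "Q1"}

    def test_threshold_not_stricter_rejected(self):
        spans = spans_from("ab", {("a", "b"): (0.9, 0.9)})
        with pytest.raises(ValueError):
            assign_subclusters(["a", "b"], spans, 0.4)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        seqs = [GenomeSequence(f"g{i}", random_seq(rng, 151)) for i in range(3)]
        path = tmp_path / "g.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_span_matrix_diag_and_symmetric_ids(self):
        rng = np.random.default_rng(4)
        seqs = [GenomeSequence(f"g{i}", random_seq(rng, 200)) for i in range(3)]
        mat = similarity_span_matrix(seqs, 10)
        assert np.all(np.diag(mat.span_frac) == 1.0)
        assert mat.genomes == ["g0", "g1", "g2"]
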