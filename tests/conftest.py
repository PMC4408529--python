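import pytest

from phagepan import GeneAssignment, build_pham_table


def make_table(genome_phams: dict[str, list[str]]):
    """Build a PhamTable from {genome: [pham, ...]} with one gene per entry."""
    assignments = [
        GeneAssignment(g, f"{g}_gene{i}", p)
        for g, phams in genome_phams.items()
        for i, p in enumerate(phams)
    ]
    return build_pham_table(assignments)


@pytest.fixture
def abc_cluster():
    """Three genomes sharing a 2-pham core: the worked example for
    CAP = 66.67, CPV = 60, CCI = 60."""
    return make_table({
        "A": ["P1", "P2", "P3"],
        "B": ["P1", "P2", "P4"],
        "C": ["P1", "P2", "P5"],
    })


@pytest.fixture
def pair_4_6():
    """Two genomes with pham sets {P1..P4} and {P3..P8}: shared percent
    100 * mean(2/4, 2/6) = 41.67."""
    return make_table({
        "a": ["P1", "P2", "P3", "P4"],
        "b": ["P3", "P4", "P5", "P6", "P7", "P8"],
    })
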