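import pytest

from seqgraph import (
    GenomeGraph,
    SequenceNode,
    build_genome_graph,
    make_fixture_set,
)


@pytest.fixture
def single_node_graph():
    g = GenomeGraph(isolates=["A"])
    g.add_node(SequenceNode("n1", "ACGT", {"A"}, {"A": (1, 4)}))
    return g


@pytest.fixture
def insertion_graph():
    """Two isolates; isolate long carries a 9 bp insertion between the
    shared flanks (the classic repeat-expansion shape)."""
    g = GenomeGraph(isolates=["short", "long"])
    g.add_node(SequenceNode("n1", "ACCTGATTGC", {"short", "long"},
                            {"short": (1, 10), "long": (1, 10)}))
    g.add_node(SequenceNode("n2", "ATGATGATG", {"long"}, {"long": (11, 19)}))
    g.add_node(SequenceNode("n3", "GGCTTACCGT", {"short", "long"},
                            {"short": (11, 20), "long": (20, 29)}))
    g.add_edge("n1", "n2", {"long"})
    g.add_edge("n2", "n3", {"long"})
    g.add_edge("n1", "n3", {"short"})
    return g


@pytest.fixture(scope="session")
def fixture_set():
    """Five 10 kb genomes: SNPs, short indels, one inversion; isolate 1 is
    the unmutated root."""
    return make_fixture_set(5, root_length=10000, seed=42)


@pytest.fixture(scope="session")
def fixture_graph(fixture_set):
    return build_genome_graph(
        fixture_set.genomes, decomposition=fixture_set.decomposition()
    )
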