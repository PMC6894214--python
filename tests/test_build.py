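"""Graph construction: XMFA parsing, structural graph, collapse, splice."""

import pytest

from seqgraph import (
    AlignedBlock,
    AlignedRow,
    BlockDecomposition,
    SpliceError,
    XMFAError,
    build_genome_graph,
    build_structure_graph,
    collapse_block,
    make_fixture_set,
    parse_xmfa,
    splice_subgraph,
)
from seqgraph._seq import revcomp


def write(path, text):
    path.write_text(text)
    return str(path)


class TestParseXMFA:
    def test_single_block_single_genome(self, tmp_path):
        xmfa = write(tmp_path / "a.xmfa", "> 1:1-8 + g\nACGTACGT\n=\n")
        decomp = parse_xmfa(xmfa, ["g"], {"g": "ACGTACGT"})
        assert len(decomp.blocks) == 1
        row = decomp.blocks[0].rows[0]
        assert (row.isolate, row.start, row.end, row.strand) == ("g", 1, 8, "+")

    def test_minus_strand_row_is_reverse_complement_of_slice(self, tmp_path):
        g1 = "AAAATTCCGGAAAA"
        g2 = "AAAA" + revcomp("TTCCGG") + "AAAA"
        body = "> 1:1-4 + a\nAAAA\n> 2:1-4 + b\nAAAA\n=\n" \
               "> 1:5-10 + a\nTTCCGG\n> 2:5-10 - b\nTTCCGG\n=\n" \
               "> 1:11-14 + a\nAAAA\n> 2:11-14 + b\nAAAA\n=\n"
        xmfa = write(tmp_path / "b.xmfa", body)
        decomp = parse_xmfa(xmfa, ["a", "b"], {"a": g1, "b": g2})
        row = decomp.blocks[1].row_for("b")
        assert row.strand == "-"
        assert row.ungapped() == revcomp(g2[row.start - 1 : row.end])

    def test_coverage_gap_synthesizes_singleton_block(self, tmp_path):
        g = "A" * 50 + "C" * 10 + "G" * 40
        body = f"> 1:1-50 + g\n{'A'*50}\n=\n> 1:61-100 + g\n{'G'*40}\n=\n"
        xmfa = write(tmp_path / "c.xmfa", body)
        decomp = parse_xmfa(xmfa, ["g"], {"g": g})
        assert len(decomp.blocks) == 3
        gap = decomp.blocks[2].rows[0]
        assert (gap.start, gap.end, gap.ungapped()) == (51, 60, "C" * 10)

    def test_malformed_header(self, tmp_path):
        xmfa = write(tmp_path / "d.xmfa", ">1_oops\nACGT\n=\n")
        with pytest.raises(XMFAError, match="malformed"):
            parse_xmfa(xmfa, ["g"], {"g": "ACGT"})

    def test_overlapping_coverage_rejected(self, tmp_path):
        body = "> 1:1-6 + g\nACGTAC\n=\n> 1:5-8 + g\nACGT\n=\n"
        xmfa = write(tmp_path / "e.xmfa", body)
        with pytest.raises(XMFAError, match="overlap"):
            parse_xmfa(xmfa, ["g"], {"g": "ACGTACGT"})

    def test_row_must_match_its_genome(self, tmp_path):
        xmfa = write(tmp_path / "f.xmfa", "> 1:1-4 + g\nTTTT\n=\n")
        with pytest.raises(XMFAError, match="does not match"):
            parse_xmfa(xmfa, ["g"], {"g": "ACGT"})


class TestStructureGraph:
    def test_single_block_two_isolates(self):
        block = AlignedBlock("Aln_1", [
            AlignedRow("a", "ACGT", 1, 4, "+"),
            AlignedRow("b", "ACGT", 1, 4, "+"),
        ])
        g = build_structure_graph(BlockDecomposition([block], {"a": 4, "b": 4}))
        assert (g.n_nodes, g.n_edges) == (1, 0)

    def test_inverted_block_is_one_node_with_negative_reversed_coords(self):
        fx = make_fixture_set(
            2, root_length=2000,
            rates={"sub_rate": 0, "ins_rate": 0, "del_rate": 0, "inv_count": 1},
            seed=7,
        )
        g = build_structure_graph(fx.decomposition())
        assert g.n_nodes == 3
        inverted = [n for n in g.nodes() if n.is_inverted("iso2")]
        assert len(inverted) == 1
        node = inverted[0]
        l, r = node.coords["iso2"]
        assert l < 0 and r < 0 and abs(l) >= abs(r)
        assert node.coords["iso1"][0] > 0  # first isolate stays forward

    def test_edges_follow_each_isolates_genomic_order(self, fixture_set):
        decomp = fixture_set.decomposition()
        g = build_structure_graph(decomp)
        for iso in fixture_set.names:
            placed = sorted(
                (n.abs_interval(iso)[0], n.name) for n in g.nodes_for_isolate(iso)
            )
            for (_, u), (_, v) in zip(placed, placed[1:]):
                assert g.has_edge(u, v) and iso in g.edge_ids(u, v)


class TestCollapse:
    def test_tandem_insertion_collapses_to_three_nodes(self):
        flank5, flank3 = "ACCTGATTGC", "GGCTTACCGT"
        short = flank5 + "ATG" * 2 + flank3
        longr = flank5 + "ATG" * 5 + flank3
        block = AlignedBlock("Aln_1", [
            AlignedRow("s1", short[:16] + "-" * 9 + short[16:], 1, len(short), "+"),
            AlignedRow("s2", longr, 1, len(longr), "+"),
        ])
        sub = collapse_block(block)
        assert sub.n_nodes == 3
        middle = sub.node("Aln_1_2")
        assert middle.ids == {"s2"}
        assert middle.sequence == "ATG" * 3

    def test_identical_rows_collapse_to_single_node_keeping_block_name(self):
        block = AlignedBlock("Aln_9", [
            AlignedRow("a", "ACGTACGT", 1, 8, "+"),
            AlignedRow("b", "ACGTACGT", 1, 8, "+"),
        ])
        sub = collapse_block(block)
        assert sub.n_nodes == 1 and sub.n_edges == 0
        assert sub.node("Aln_9").ids == {"a", "b"}

    def test_single_substitution_yields_four_sequentially_named_nodes(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + "T" + a[11:]
        block = AlignedBlock("Aln_66", [
            AlignedRow("a", a, 1, 20, "+"),
            AlignedRow("b", b, 1, 20, "+"),
        ])
        sub = collapse_block(block)
        assert sorted(n.name for n in sub.nodes()) == [
            "Aln_66_1", "Aln_66_2", "Aln_66_3", "Aln_66_4"
        ]
        variant = [n for n in sub.nodes() if len(n.ids) == 1]
        assert {frozenset(n.ids) for n in variant} == {frozenset({"a"}), frozenset({"b"})}

    def test_parallel_nodes_per_column_equal_distinct_characters(self):
        block = AlignedBlock("Aln_1", [
            AlignedRow("a", "AAAA", 1, 4, "+"),
            AlignedRow("b", "ACAA", 1, 4, "+"),
            AlignedRow("c", "AGAA", 1, 4, "+"),
        ])
        sub = collapse_block(block)
        # shared prefix, 3 parallel variant nodes, shared suffix
        assert sub.n_nodes == 5

    def test_each_row_path_spells_its_sequence(self, fixture_set):
        decomp = fixture_set.decomposition()
        block = next(b for b in decomp.blocks if len(b.rows) == len(fixture_set.names))
        sub = collapse_block(block, isolate_order=fixture_set.names)
        for row in block.rows:
            walk = sub.isolate_walk(row.isolate)
            rebuilt = "".join(
                sub.node(name).forward_segment(row.isolate) for name, _ in walk
            )
            lo = min(n.abs_interval(row.isolate)[0] for n in sub.nodes_for_isolate(row.isolate))
            genome = fixture_set.genomes[row.isolate]
            assert rebuilt == genome[lo - 1 : lo - 1 + len(rebuilt)]


class TestSplice:
    def _chain(self):
        from seqgraph import GenomeGraph, SequenceNode

        g = GenomeGraph(isolates=["a", "b"])
        g.add_node(SequenceNode("Aln_1", "AAAA", {"a", "b"},
                                {"a": (1, 4), "b": (1, 4)}))
        g.add_node(SequenceNode("Aln_2", "CCCC", {"a", "b"},
                                {"a": (5, 8), "b": (5, 8)}))
        g.add_node(SequenceNode("Aln_3", "GGGG", {"a", "b"},
                                {"a": (9, 12), "b": (9, 12)}))
        g.add_edge("Aln_1", "Aln_2", {"a", "b"})
        g.add_edge("Aln_2", "Aln_3", {"a", "b"})
        return g

    def test_identity_splice_leaves_graph_unchanged(self):
        g = self._chain()
        block = AlignedBlock("Aln_2", [
            AlignedRow("a", "CCCC", 5, 8, "+"),
            AlignedRow("b", "CCCC", 5, 8, "+"),
        ])
        sub = collapse_block(block)
        before = (g.n_nodes, g.n_edges)
        splice_subgraph(g, "Aln_2", sub)
        assert (g.n_nodes, g.n_edges) == before
        g.validate()

    def test_splicing_a_variant_subgraph_keeps_walks_intact(self):
        g = self._chain()
        block = AlignedBlock("Aln_2", [
            AlignedRow("a", "CCCC", 5, 8, "+"),
            AlignedRow("b", "CGCC", 5, 8, "+"),
        ])
        sub = collapse_block(block)
        splice_subgraph(g, "Aln_2", sub)
        g.validate()
        assert g.reconstruct_sequence("a") == "AAAACCCCGGGG"
        assert g.reconstruct_sequence("b") == "AAAACGCCGGGG"

    def test_span_mismatch_rejected(self):
        g = self._chain()
        block = AlignedBlock("Aln_2", [
            AlignedRow("a", "CCCC", 6, 9, "+"),
            AlignedRow("b", "CCCC", 5, 8, "+"),
        ])
        sub = collapse_block(block)
        with pytest.raises(SpliceError, match="span"):
            splice_subgraph(g, "Aln_2", sub)

    def test_isolate_set_mismatch_rejected(self):
        g = self._chain()
        block = AlignedBlock("Aln_2", [AlignedRow("a", "CCCC", 5, 8, "+")])
        sub = collapse_block(block)
        with pytest.raises(SpliceError, match="isolates"):
            splice_subgraph(g, "Aln_2", sub)


class TestBuildGenomeGraph:
    def test_single_genome_round_trips(self):
        g = build_genome_graph({"only": "ACGTACGTTGCA"})
        assert g.reconstruct_sequence("only") == "ACGTACGTTGCA"

    def test_tandem_insertion_pair_gives_three_nodes(self):
        flank5, flank3 = "ACCTGATTGCGTATCGATTA", "GGCTTACCGTAGGACCTAAG"
        s1 = flank5 + "ATG" * 2 + flank3
        s2 = flank5 + "ATG" * 5 + flank3
        g = build_genome_graph({"s1": s1, "s2": s2})
        assert g.n_nodes == 3
        private = [n for n in g.nodes() if n.ids == {"s2"}]
        assert len(private) == 1 and len(private[0].sequence) == 9

    def test_round_trip_via_truth_decomposition(self, fixture_set, fixture_graph):
        for iso in fixture_set.names:
            assert fixture_graph.reconstruct_sequence(iso) == fixture_set.genomes[iso]

    def test_round_trip_via_xmfa_file(self, tmp_path, fixture_set):
        xmfa = tmp_path / "fx.xmfa"
        fixture_set.write_xmfa(xmfa)
        g = build_genome_graph(fixture_set.genomes, xmfa=str(xmfa))
        for iso in fixture_set.names:
            assert g.reconstruct_sequence(iso) == fixture_set.genomes[iso]

    def test_inversion_reconstruction_reverse_complements(self):
        fx = make_fixture_set(
            2, root_length=1500,
            rates={"sub_rate": 0, "ins_rate": 0, "del_rate": 0, "inv_count": 1},
            seed=11,
        )
        g = build_genome_graph(fx.genomes, decomposition=fx.decomposition())
        (iso, ev), = fx.all_inversions()
        assert iso == "iso2"
        assert g.reconstruct_sequence("iso2") == fx.genomes["iso2"]
        segment = fx.genomes["iso2"][ev.root_start - 1 : ev.root_end]
        assert segment == revcomp(fx.root[ev.root_start - 1 : ev.root_end])

    def test_no_mutations_collapse_to_single_node(self):
        fx = make_fixture_set(
            4, root_length=800,
            rates={"sub_rate": 0, "ins_rate": 0, "del_rate": 0, "inv_count": 0},
            seed=3,
        )
        g = build_genome_graph(fx.genomes, decomposition=fx.decomposition())
        assert g.n_nodes == 1

    def test_splice_preserves_per_isolate_length(self, fixture_set, fixture_graph):
        for iso in fixture_set.names:
            total = sum(
                len(n.sequence) for n in fixture_graph.nodes_for_isolate(iso)
            )
            assert total == len(fixture_set.genomes[iso])
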