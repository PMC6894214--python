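"""Graph queries: extraction, liftover, conserved regions, homology."""

import numpy as np
import pytest

from seqgraph import (
    FeatureRecord,
    GenomeGraph,
    QueryError,
    SequenceNode,
    build_genome_graph,
    extract_gene_sequence,
    extract_gene_subgraph,
    extract_subsequence,
    homology_matrix,
    isolate_specific_nodes,
    largest_conserved_node,
    make_fixture_set,
    make_homology_fixture,
    read_features,
    translate_position,
)
from seqgraph._seq import revcomp


def feature(isolate, start, end, strand="+", gene="g1"):
    return FeatureRecord(isolate, isolate, "gene", start, end, strand,
                         {"gene_id": gene})


class TestExtractSubsequence:
    def test_whole_genome_equals_reconstruction(self, fixture_set, fixture_graph):
        iso = fixture_set.names[2]
        L = len(fixture_set.genomes[iso])
        assert extract_subsequence(fixture_graph, iso, 1, L) == fixture_set.genomes[iso]

    def test_interval_inside_one_forward_node(self, single_node_graph):
        assert extract_subsequence(single_node_graph, "A", 2, 3) == "CG"

    def test_random_intervals_match_full_reconstruction(self, fixture_set, fixture_graph):
        rng = np.random.default_rng(0)
        iso = "iso4"  # the isolate carrying the inversion in this fixture
        genome = fixture_set.genomes[iso]
        inv = fixture_set.truths[iso].inversions()[0]
        for _ in range(100):
            start = int(rng.integers(1, len(genome)))
            end = int(rng.integers(start, len(genome) + 1))
            assert extract_subsequence(fixture_graph, iso, start, end) == genome[start - 1 : end]
        # intervals straddling the inverted segment
        for _ in range(20):
            start = int(rng.integers(max(1, inv.root_start - 50), inv.root_start + 1))
            end = int(rng.integers(inv.root_end, min(len(genome), inv.root_end + 50) + 1))
            assert extract_subsequence(fixture_graph, iso, start, end) == genome[start - 1 : end]

    def test_out_of_range_rejected(self, single_node_graph):
        with pytest.raises(QueryError, match="out of range"):
            extract_subsequence(single_node_graph, "A", 2, 9)


class TestGeneExtraction:
    def test_plus_strand_gene_inside_one_node(self, single_node_graph):
        assert extract_gene_sequence(single_node_graph, feature("A", 1, 3)) == "ACG"

    def test_minus_strand_gene_is_reverse_complement(self, single_node_graph):
        plus = extract_gene_sequence(single_node_graph, feature("A", 1, 3, "+"))
        minus = extract_gene_sequence(single_node_graph, feature("A", 1, 3, "-"))
        assert minus == revcomp(plus)

    def test_genes_across_node_boundaries_match_truth(self):
        fixture, annotations, _ = make_homology_fixture(seed=9)
        graph = build_genome_graph(fixture.genomes, decomposition=fixture.decomposition())
        for iso, features in annotations.items():
            genome = fixture.genomes[iso]
            for f in features:
                expected = genome[f.start - 1 : f.end]
                if f.strand == "-":
                    expected = revcomp(expected)
                assert extract_gene_sequence(graph, f) == expected


class TestGeneSubgraph:
    def test_identical_gene_yields_single_universal_node(self):
        fx = make_fixture_set(
            3, root_length=600,
            rates={"sub_rate": 0, "ins_rate": 0, "del_rate": 0, "inv_count": 0},
            seed=1,
        )
        g = build_genome_graph(fx.genomes, decomposition=fx.decomposition())
        sub = extract_gene_subgraph(g, feature("iso1", 100, 200))
        assert sub.n_nodes == 1
        assert next(iter(sub.nodes())).ids == set(fx.names)

    def test_gene_over_snp_contains_parallel_variant_nodes(self):
        flanks = ("ACCTGATTGCGTATCGATTA", "GGCTTACCGTAGGACCTAAG")
        a = flanks[0] + "A" + flanks[1]
        b = flanks[0] + "C" + flanks[1]
        g = build_genome_graph({"a": a, "b": b})
        sub = extract_gene_subgraph(g, feature("a", 10, 30))
        assert sub.n_nodes >= 4
        assert sum(1 for n in sub.nodes() if len(n.ids) == 1) == 2

    def test_whole_genome_feature_covers_whole_graph(self, fixture_set, fixture_graph):
        iso = fixture_set.names[0]
        sub = extract_gene_subgraph(
            fixture_graph, feature(iso, 1, len(fixture_set.genomes[iso]))
        )
        assert set(sub.node_names()) == set(fixture_graph.node_names())


class TestTranslatePosition:
    def test_identity(self, fixture_graph):
        assert translate_position(fixture_graph, 1234, "iso2", "iso2") == 1234

    def test_untouched_positions_map_via_truth_offsets(self, fixture_set, fixture_graph):
        truth = fixture_set.truths["iso3"]
        touched = [(e.root_start - 1, e.root_end + 1) for e in truth.events]
        for pos in range(1, truth.root_length + 1, 97):
            if any(a <= pos <= b for a, b in touched):
                continue
            expected = truth.root_to_derived(pos)
            got = translate_position(fixture_graph, pos, "iso1", "iso3")
            assert got is not None and abs(got) == expected

    def test_insertion_shifts_downstream_positions(self):
        flanks = ("ACCTGATTGCGTATCGATTA", "GGCTTACCGTAGGACCTAAG")
        a = flanks[0] + flanks[1]
        b = flanks[0] + "TTGCAA" + flanks[1]  # 6 bp insertion in b
        g = build_genome_graph({"a": a, "b": b})
        assert translate_position(g, 25, "a", "b") == 31
        assert translate_position(g, 31, "b", "a") == 25

    def test_position_in_private_insertion_is_absent(self):
        flanks = ("ACCTGATTGCGTATCGATTA", "GGCTTACCGTAGGACCTAAG")
        a = flanks[0] + "TTGCAA" + flanks[1]
        b = flanks[0] + flanks[1]
        g = build_genome_graph({"a": a, "b": b})
        assert translate_position(g, 23, "a", "b") is None

    def test_inverted_node_flips_sign_and_preserves_base_homology(self):
        g = GenomeGraph(isolates=["A", "B"])
        g.add_node(SequenceNode("n1", "AACCGGTT", {"A", "B"},
                                {"A": (1, 8), "B": (-8, -1)}))
        got = translate_position(g, 2, "A", "B")
        assert got == -7  # same base, opposite orientation
        assert translate_position(g, 7, "B", "A") == -2

    def test_round_trip_is_identity_where_defined(self, fixture_set, fixture_graph):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = int(rng.integers(1, len(fixture_set.genomes["iso1"]) + 1))
            fwd = translate_position(fixture_graph, pos, "iso1", "iso5")
            if fwd is None:
                continue
            back = translate_position(fixture_graph, abs(fwd), "iso5", "iso1")
            assert back is not None and abs(back) == pos


class TestConservedAndPrivateNodes:
    def test_single_node_graph_is_its_own_conserved_node(self, single_node_graph):
        assert largest_conserved_node(single_node_graph).name == "n1"

    def test_conserved_run_found_in_fixture(self, fixture_set, fixture_graph):
        node = largest_conserved_node(fixture_graph)
        assert node is not None and node.ids == set(fixture_set.names)
        # the node's span carries no substitutions or indels in any isolate;
        # a spanning inversion is allowed (inverted homologous sequence
        # stays in one shared node — that is the model's point)
        lo, hi = node.abs_interval("iso1")
        for iso in fixture_set.names[1:]:
            for ev in fixture_set.truths[iso].events:
                if ev.kind == "inversion" and ev.root_start <= lo and hi <= ev.root_end:
                    continue
                assert ev.root_end < lo or ev.root_start > hi

    def test_no_universal_node_returns_none(self, insertion_graph):
        # remove the shared nodes' universality by querying a graph where
        # every node misses an isolate
        g = GenomeGraph(isolates=["A", "B"])
        g.add_node(SequenceNode("x", "AAAA", {"A"}, {"A": (1, 4)}))
        g.add_node(SequenceNode("y", "CCCC", {"B"}, {"B": (1, 4)}))
        assert largest_conserved_node(g) is None

    def test_private_snp_nodes_reported(self):
        flanks = ("ACCTGATTGCGTATCGATTA", "GGCTTACCGTAGGACCTAAG")
        a = flanks[0] + "A" + flanks[1]
        b = flanks[0] + "C" + flanks[1]
        g = build_genome_graph({"a": a, "b": b})
        hits = isolate_specific_nodes(g)
        assert {n.sequence for n in hits} == {"A", "C"}

    def test_length_threshold_is_strict(self):
        g = GenomeGraph(isolates=["A", "B"])
        g.add_node(SequenceNode("shared", "AAAA", {"A", "B"},
                                {"A": (1, 4), "B": (1, 4)}))
        g.add_node(SequenceNode("len3", "CCC", {"A"}, {"A": (5, 7)}))
        g.add_node(SequenceNode("len2", "GG", {"B"}, {"B": (5, 6)}))
        hits = isolate_specific_nodes(g, max_len=3)
        assert [n.name for n in hits] == ["len2"]


class TestHomologyMatrix:
    def test_isolate_against_itself_is_identity(self):
        fixture, annotations, _ = make_homology_fixture(seed=2, n_genomes=2)
        graph = build_genome_graph(fixture.genomes, decomposition=fixture.decomposition())
        ann = {"iso1": annotations["iso1"]}
        hm = homology_matrix(graph, ann)
        assert list(hm.table["iso1"]) == list(hm.table.index)

    def test_three_isolate_truth_recovered_with_paralogues(self):
        fixture, annotations, expected = make_homology_fixture(seed=3)
        graph = build_genome_graph(fixture.genomes, decomposition=fixture.decomposition())
        hm = homology_matrix(graph, annotations)
        assert hm.table.equals(expected)

    def test_symmetric_under_reference_swap(self):
        fixture, annotations, _ = make_homology_fixture(seed=4, n_genomes=2)
        graph = build_genome_graph(fixture.genomes, decomposition=fixture.decomposition())
        fwd = homology_matrix(graph, annotations, ref_isolate="iso1")
        rev = homology_matrix(graph, annotations, ref_isolate="iso2")
        mapping = dict(zip(fwd.table.index, fwd.table["iso2"]))
        back = dict(zip(rev.table["iso1"], rev.table.index))
        for g1, g2 in mapping.items():
            assert back.get(g1) == g2

    def test_annotation_outside_genome_rejected(self, fixture_graph):
        bad = [feature("iso1", 1, 10**7)]
        with pytest.raises(QueryError, match="beyond genome length"):
            homology_matrix(fixture_graph, {"iso1": bad})


class TestFeatureIO:
    def test_read_gtf_features(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t10\t50\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\tCDS\t12\t48\t.\t-\t.\tgene_id "g1";\n'
        )
        feats = read_features(gtf, "isoX", feature_types=("gene",))
        assert len(feats) == 1
        f = feats[0]
        assert (f.isolate, f.start, f.end, f.strand, f.gene_id) == ("isoX", 10, 50, "+", "g1")

    def test_read_gff3_features(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t5\t25\t.\t-\t.\tID=geneA;Name=carB\n"
        )
        feats = read_features(gff, "isoY")
        assert feats[0].gene_id == "geneA"
        assert feats[0].strand == "-"
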