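"""Downstream analyses on a built genome graph.

The per-isolate coordinate system stored on every node makes these queries
annotation-aware: a GTF/GFF interval on one isolate locates the nodes it
covers, from which sequence extraction, coordinate liftover to other
isolates, and position-based (rather than similarity-based) orthologue
mapping all follow.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from gffutils.iterators import DataIterator

from ._seq import revcomp
from .model import GenomeGraph, GraphError, SequenceNode


class QueryError(GraphError):
    pass


@dataclass
class FeatureRecord:
    """One annotation interval (gene/CDS) on a named isolate.

    ``start``/``end`` are 1-based inclusive on the isolate's forward strand;
    ``attributes`` must carry a gene identifier under ``gene_id``, ``ID`` or
    ``locus_tag``.
    """

    isolate: str
    seqid: str
    feature_type: str
    start: int
    end: int
    strand: str
    attributes: Dict[str, str] = field(default_factory=dict)

    @property
    def gene_id(self) -> str:
        for key in ("gene_id", "ID", "locus_tag", "Name"):
            if key in self.attributes:
                return self.attributes[key]
        raise QueryError(
            f"feature on {self.isolate!r} [{self.start}, {self.end}] has no gene "
            f"identifier (gene_id/ID/locus_tag)"
        )

    def validate(self, genome_length: Optional[int] = None) -> None:
        if not (1 <= self.start <= self.end):
            raise QueryError(
                f"feature {self.attributes}: invalid interval ({self.start}, {self.end})"
            )
        if genome_length is not None and self.end > genome_length:
            raise QueryError(
                f"feature ends at {self.end}, beyond genome length {genome_length} "
                f"of isolate {self.isolate!r}"
            )
        if self.strand not in "+-":
            raise QueryError(f"feature strand must be '+' or '-', got {self.strand!r}")


def read_features(path, isolate: str, feature_types: Optional[Iterable[str]] = None) -> List[FeatureRecord]:
    """Read GTF/GFF3 annotations for ``isolate`` into FeatureRecords.

    ``feature_types`` filters on column 3 (e.g. ``("gene", "CDS")``); by
    default every feature line is returned.
    """
    wanted = set(feature_types) if feature_types else None
    records = []
    for f in DataIterator(str(path)):
        if wanted and f.featuretype not in wanted:
            continue
        attributes = {k: v[0] for k, v in f.attributes.items() if v}
        records.append(
            FeatureRecord(
                isolate=isolate,
                seqid=f.seqid,
                feature_type=f.featuretype,
                start=int(f.start),
                end=int(f.end),
                strand=f.strand if f.strand in "+-" else "+",
                attributes=attributes,
            )
        )
    return records


def _sorted_nodes(graph: GenomeGraph, isolate: str) -> List[SequenceNode]:
    if isolate not in graph.isolates:
        raise QueryError(f"unknown isolate {isolate!r}")
    return sorted(graph.nodes_for_isolate(isolate), key=lambda n: n.abs_interval(isolate)[0])


def _overlapping_nodes(
    graph: GenomeGraph, isolate: str, start: int, end: int
) -> List[SequenceNode]:
    nodes = _sorted_nodes(graph, isolate)
    los = [n.abs_interval(isolate)[0] for n in nodes]
    i = bisect_right(los, start) - 1
    if i < 0:
        i = 0
    out = []
    for n in nodes[i:]:
        lo, hi = n.abs_interval(isolate)
        if lo > end:
            break
        if hi >= start:
            out.append(n)
    return out


def extract_subsequence(graph: GenomeGraph, isolate: str, start: int, end: int) -> str:
    """Forward-strand sequence of ``isolate`` over ``[start, end]`` (1-based,
    inclusive), assembled from the covering nodes without reconstructing the
    whole genome."""
    length = graph.genome_length(isolate)
    if not (1 <= start <= end <= length):
        raise QueryError(
            f"interval [{start}, {end}] out of range for {isolate!r} (length {length})"
        )
    pieces = []
    for node in _overlapping_nodes(graph, isolate, start, end):
        lo, hi = node.abs_interval(isolate)
        segment = node.forward_segment(isolate)
        pieces.append(segment[max(start, lo) - lo : min(end, hi) - lo + 1])
    return "".join(pieces)


def extract_gene_sequence(graph: GenomeGraph, feature: FeatureRecord) -> str:
    """Gene sequence for ``feature``; reverse-complemented for '-' strand."""
    feature.validate(graph.genome_length(feature.isolate))
    seq = extract_subsequence(graph, feature.isolate, feature.start, feature.end)
    return revcomp(seq) if feature.strand == "-" else seq


def extract_gene_subgraph(graph: GenomeGraph, feature: FeatureRecord) -> GenomeGraph:
    """Induced subgraph of all nodes overlapping ``feature`` on its isolate.

    The result carries a ``seq_len`` node attribute on export (useful for
    sizing nodes in viewers such as Cytoscape): a single universal node means
    the gene is identical across all isolates.
    """
    feature.validate(graph.genome_length(feature.isolate))
    covering = _overlapping_nodes(graph, feature.isolate, feature.start, feature.end)
    names = {n.name for n in covering}
    # pull in the other isolates' parallel variant nodes over the same
    # region, so alternative alleles are visible in the exported subgraph
    spans: Dict[str, Tuple[int, int]] = {}
    for node in covering:
        for isolate in node.ids:
            lo, hi = node.abs_interval(isolate)
            if isolate in spans:
                spans[isolate] = (min(spans[isolate][0], lo), max(spans[isolate][1], hi))
            else:
                spans[isolate] = (lo, hi)
    for isolate, (lo, hi) in spans.items():
        if isolate != feature.isolate:
            names.update(n.name for n in _overlapping_nodes(graph, isolate, lo, hi))
    sub = graph.subgraph(names)
    sub.metadata["seq_len_attr"] = "1"
    sub.metadata["feature"] = f"{feature.isolate}:{feature.start}-{feature.end}"
    return sub


def _node_seq_index(node: SequenceNode, isolate: str, pos: int) -> int:
    """Index into the stored node sequence of forward-strand position ``pos``."""
    l, r = node.coords[isolate]
    if l > 0:
        return pos - l
    return abs(l) - pos  # stored sequence runs from forward position |l| down to |r|


def translate_position(
    graph: GenomeGraph, pos: int, from_isolate: str, to_isolate: str
) -> Optional[int]:
    """Lift a forward-strand position from one isolate to another.

    Returns the position in ``to_isolate`` at the same aligned base, or
    ``None`` when the position falls in sequence absent from ``to_isolate``
    (no interpolation is attempted).  The result is negated when the two
    isolates carry the node in opposite orientations.
    """
    length = graph.genome_length(from_isolate)
    if not (1 <= pos <= length):
        raise QueryError(
            f"position {pos} out of range for {from_isolate!r} (length {length})"
        )
    if to_isolate not in graph.isolates:
        raise QueryError(f"unknown isolate {to_isolate!r}")
    nodes = _overlapping_nodes(graph, from_isolate, pos, pos)
    node = nodes[0]
    if to_isolate not in node.ids:
        return None
    k = _node_seq_index(node, from_isolate, pos)
    l2, r2 = node.coords[to_isolate]
    out = l2 + k if l2 > 0 else abs(l2) - k
    same_orientation = (node.coords[from_isolate][0] > 0) == (l2 > 0)
    return out if same_orientation else -out


def largest_conserved_node(graph: GenomeGraph) -> Optional[SequenceNode]:
    """The longest node shared by every isolate (ties: smallest name), or
    ``None`` when no node is universal."""
    if graph.n_nodes == 0:
        raise QueryError("empty graph")
    universal = [n for n in graph.nodes() if n.ids == set(graph.isolates)]
    if not universal:
        return None
    return min(universal, key=lambda n: (-len(n.sequence), n.name))


def isolate_specific_nodes(
    graph: GenomeGraph, max_len: int = 3, exclusive: bool = True
) -> List[SequenceNode]:
    """Short private nodes — isolate-specific SNPs and micro-indels.

    Returns nodes with sequence length strictly less than ``max_len`` that
    belong to exactly one isolate (``exclusive=True``) or that are missing
    from at least one isolate (``exclusive=False``), sorted by isolate then
    coordinate.
    """
    if max_len < 1:
        raise QueryError("max_len must be >= 1")
    all_ids = set(graph.isolates)
    hits = []
    for node in graph.nodes():
        if len(node.sequence) >= max_len:
            continue
        if exclusive and len(node.ids) != 1:
            continue
        if not exclusive and node.ids == all_ids:
            continue
        iso = min(node.ids)
        hits.append((iso, node.abs_interval(iso)[0], node))
    return [n for _, _, n in sorted(hits, key=lambda t: (t[0], t[1]))]


# -- homology matrix ---------------------------------------------------------


def gene_footprint(
    graph: GenomeGraph, feature: FeatureRecord
) -> Dict[str, Tuple[int, int]]:
    """The gene's graph footprint: per covered node, the inclusive interval
    of stored-sequence indices the gene occupies."""
    feature.validate(graph.genome_length(feature.isolate))
    footprint = {}
    for node in _overlapping_nodes(graph, feature.isolate, feature.start, feature.end):
        lo, hi = node.abs_interval(feature.isolate)
        a, b = max(feature.start, lo), min(feature.end, hi)
        ka = _node_seq_index(node, feature.isolate, a)
        kb = _node_seq_index(node, feature.isolate, b)
        footprint[node.name] = (min(ka, kb), max(ka, kb))
    return footprint


def _shared_length(
    fa: Mapping[str, Tuple[int, int]], fb: Mapping[str, Tuple[int, int]]
) -> int:
    shared = 0
    for name, (a1, a2) in fa.items():
        if name in fb:
            b1, b2 = fb[name]
            shared += max(0, min(a2, b2) - max(a1, b1) + 1)
    return shared


def _footprint_length(fp: Mapping[str, Tuple[int, int]]) -> int:
    return sum(b - a + 1 for a, b in fp.values())


@dataclass
class HomologyMatrix:
    """Gene-by-isolate orthologue table, position-based.

    ``table`` rows are gene ids of the reference isolate; columns are
    isolates; cells hold the matched gene id or ``None``.
    """

    ref_isolate: str
    table: pd.DataFrame
    overlap_threshold: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene", na_rep=".")


def homology_matrix(
    graph: GenomeGraph,
    annotations: Mapping[str, Sequence[FeatureRecord]],
    ref_isolate: Optional[str] = None,
    overlap_threshold: float = 0.5,
) -> HomologyMatrix:
    """Map gene ids between isolates by shared graph footprint.

    Two genes match when the length of sequence their footprints share
    within the graph is at least ``overlap_threshold`` times the shorter
    footprint; each gene is matched to at most one gene per other isolate
    (greedy by descending shared length, ties by gene id).  Because matching
    is positional, paralogues at distinct loci resolve to their positional
    counterparts regardless of sequence identity.
    """
    if not annotations:
        raise QueryError("no annotations supplied")
    ref = ref_isolate or next(
        i for i in graph.isolates if i in annotations
    )
    if ref not in annotations:
        raise QueryError(f"no annotations for reference isolate {ref!r}")

    footprints: Dict[str, Dict[str, Dict[str, Tuple[int, int]]]] = {}
    for isolate, features in annotations.items():
        per_gene = {}
        for feature in features:
            if feature.isolate != isolate:
                raise QueryError(
                    f"feature {feature.gene_id!r} labelled {feature.isolate!r} listed "
                    f"under {isolate!r}"
                )
            per_gene[feature.gene_id] = gene_footprint(graph, feature)
        footprints[isolate] = per_gene

    ref_genes = list(footprints[ref])
    columns: Dict[str, Dict[str, Optional[str]]] = {ref: {g: g for g in ref_genes}}
    for isolate in annotations:
        if isolate == ref:
            continue
        candidates = []
        for g_ref, f_ref in footprints[ref].items():
            for g_other, f_other in footprints[isolate].items():
                shared = _shared_length(f_ref, f_other)
                if shared <= 0:
                    continue
                shorter = min(_footprint_length(f_ref), _footprint_length(f_other))
                if shared >= overlap_threshold * shorter:
                    candidates.append((shared, g_ref, g_other))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        matched: Dict[str, Optional[str]] = {g: None for g in ref_genes}
        used = set()
        for _, g_ref, g_other in candidates:
            if matched[g_ref] is None and g_other not in used:
                matched[g_ref] = g_other
                used.add(g_other)
        columns[isolate] = matched

    order = [ref] + [i for i in annotations if i != ref]
    table = pd.DataFrame(
        {isolate: [columns[isolate][g] for g in ref_genes] for isolate in order},
        index=pd.Index(ref_genes, name="gene"),
    )
    return HomologyMatrix(ref, table, overlap_threshold)
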