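"""Genome-graph construction.

Construction is two-staged.  First a *structural* graph is built with one
temporary node per co-linear block (either from an XMFA decomposition
produced by a whole-genome aligner, or a single block covering rearrangement
free genomes).  Each multi-isolate block's gapped alignment is then
*collapsed* into a subgraph of shared-sequence nodes and variant branches,
which is spliced back in place of the temporary node.  After every build the
master invariant is checked: each isolate's walk reconstructs its input
genome byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._seq import GAP, revcomp, ungap
from ._version import __version__ as _version
from .align import (
    AlignedBlock,
    AlignedRow,
    AlignmentError,
    progressive_msa,
    run_external_aligner,
)
from .model import GenomeGraph, GraphError, SequenceNode, ValidationError


class BuildError(GraphError):
    pass


class XMFAError(BuildError):
    pass


class SpliceError(BuildError):
    pass


@dataclass
class BlockDecomposition:
    """A set of co-linear blocks tiling every genome."""

    blocks: List[AlignedBlock] = field(default_factory=list)
    genome_lengths: Dict[str, int] = field(default_factory=dict)

    @property
    def isolates(self) -> List[str]:
        return list(self.genome_lengths)

    def validate(self) -> None:
        for block in self.blocks:
            block.validate()
        for isolate, length in self.genome_lengths.items():
            intervals = sorted(
                (row.start, row.end, block.block_id)
                for block in self.blocks
                for row in block.rows
                if row.isolate == isolate
            )
            cursor = 1
            for start, end, bid in intervals:
                if start < cursor:
                    raise BuildError(
                        f"isolate {isolate!r}: block {bid!r} interval ({start}, {end}) "
                        f"overlaps coverage up to {cursor - 1}"
                    )
                if start > cursor:
                    raise BuildError(
                        f"isolate {isolate!r}: coverage gap [{cursor}, {start - 1}] "
                        f"before block {bid!r}"
                    )
                cursor = end + 1
            if cursor != length + 1:
                raise BuildError(
                    f"isolate {isolate!r}: coverage ends at {cursor - 1}, "
                    f"genome length is {length}"
                )


_XMFA_HEADER = re.compile(r"^>\s*(\d+):(\d+)-(\d+)\s*([+-])(?:\s+(.*))?$")


def parse_xmfa(path, isolates: Sequence[str], genomes: Mapping[str, str]) -> BlockDecomposition:
    """Parse an XMFA block decomposition (progressiveMauve dialect).

    Headers look like ``> 2:100-250 - comment``; the 1-based sequence index
    maps to ``isolates`` in order.  ``-`` strand rows hold the
    reverse-complement of the forward-strand slice.  Coverage gaps between
    blocks are closed by synthesising single-isolate blocks so that every
    genome is tiled completely.
    """
    isolates = list(isolates)
    genomes = {i: genomes[i].upper() for i in isolates}
    genome_lengths = {i: len(genomes[i]) for i in isolates}

    raw_blocks: List[List[Tuple[int, int, int, str, str]]] = []
    current: List[Tuple[int, int, int, str, List[str]]] = []

    def finish() -> None:
        if current:
            raw_blocks.append(
                [(idx, s, e, st, "".join(chunks)) for idx, s, e, st, chunks in current]
            )
            current.clear()

    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("="):
                finish()
                continue
            if line.startswith(">"):
                match = _XMFA_HEADER.match(line)
                if not match:
                    raise XMFAError(f"{path}:{lineno}: malformed XMFA header {line!r}")
                idx, start, end, strand = (
                    int(match.group(1)),
                    int(match.group(2)),
                    int(match.group(3)),
                    match.group(4),
                )
                if start == 0 and end == 0:
                    current.append((idx, 0, 0, strand, []))  # absent-genome stub
                    continue
                if not (1 <= idx <= len(isolates)):
                    raise XMFAError(
                        f"{path}:{lineno}: sequence index {idx} out of range "
                        f"(have {len(isolates)} isolates)"
                    )
                if start > end:
                    raise XMFAError(
                        f"{path}:{lineno}: start {start} > end {end}"
                    )
                current.append((idx, start, end, strand, []))
            else:
                if not current:
                    raise XMFAError(f"{path}:{lineno}: sequence data before any header")
                current[-1][4].append(line.strip().upper())
    finish()

    blocks: List[AlignedBlock] = []
    counter = 1
    for raw in raw_blocks:
        rows = []
        for idx, start, end, strand, gapped in raw:
            if start == 0 and end == 0:
                continue
            isolate = isolates[idx - 1]
            body = ungap(gapped)
            if len(body) != end - start + 1:
                raise XMFAError(
                    f"block {counter}: row {isolate!r} ungapped length {len(body)} != "
                    f"span {end - start + 1}"
                )
            forward = genomes[isolate][start - 1 : end]
            expected = forward if strand == "+" else revcomp(forward)
            if body != expected:
                raise XMFAError(
                    f"block {counter}: row {isolate!r} sequence does not match the "
                    f"{strand} strand slice [{start}, {end}] of its genome"
                )
            rows.append(AlignedRow(isolate, gapped, start, end, strand))
        if not rows:
            continue
        blocks.append(AlignedBlock(f"Aln_{counter}", rows))
        counter += 1

    # close per-isolate coverage gaps with singleton blocks
    for isolate in isolates:
        intervals = sorted(
            (row.start, row.end)
            for block in blocks
            for row in block.rows
            if row.isolate == isolate
        )
        cursor = 1
        gaps: List[Tuple[int, int]] = []
        for start, end in intervals:
            if start < cursor:
                raise XMFAError(
                    f"isolate {isolate!r}: overlapping block coverage at [{start}, {end}]"
                )
            if start > cursor:
                gaps.append((cursor, start - 1))
            cursor = end + 1
        if cursor <= genome_lengths[isolate]:
            gaps.append((cursor, genome_lengths[isolate]))
        for start, end in gaps:
            blocks.append(
                AlignedBlock(
                    f"Aln_{counter}",
                    [AlignedRow(isolate, genomes[isolate][start - 1 : end], start, end, "+")],
                )
            )
            counter += 1

    decomp = BlockDecomposition(blocks, genome_lengths)
    decomp.validate()
    return decomp


def normalize_block(block: AlignedBlock, isolate_order: Sequence[str]) -> AlignedBlock:
    """Flip a block so its first member isolate (by graph order) is on '+'.

    Flipping reverse-complements every gapped row (gaps stay put relative to
    the reversal) and toggles strands; forward-strand coordinates are
    orientation-free and unchanged.
    """
    present = [i for i in isolate_order if i in {r.isolate for r in block.rows}]
    if not present:
        return block
    if block.row_for(present[0]).strand == "+":
        return block
    return AlignedBlock(
        block.block_id,
        [
            AlignedRow(
                r.isolate,
                revcomp(r.gapped_seq),
                r.start,
                r.end,
                "+" if r.strand == "-" else "-",
            )
            for r in block.rows
        ],
    )


def _row_coords(row: AlignedRow, consumed: int, length: int) -> Tuple[int, int]:
    """Coordinates of a node consuming ``length`` bases of ``row`` after
    ``consumed`` bases have been consumed (in block orientation)."""
    if row.strand == "+":
        left = row.start + consumed
        return (left, left + length - 1)
    # '-' strand: the first base of the row sits at forward position row.end
    e = row.end - consumed
    return (-e, -(e - length + 1))


def build_structure_graph(
    decomp: BlockDecomposition,
    isolate_order: Optional[Sequence[str]] = None,
) -> GenomeGraph:
    """One temporary node per co-linear block, edged along each genome.

    Temporary nodes hold a representative (first-row) sequence only; they are
    replaced during collapse and are therefore not held to per-isolate span
    invariants.
    """
    decomp.validate()
    order = list(isolate_order or decomp.isolates)
    graph = GenomeGraph(isolates=order)
    for block in decomp.blocks:
        block = normalize_block(block, order)
        first = next(i for i in order if i in {r.isolate for r in block.rows})
        coords = {}
        for row in block.rows:
            coords[row.isolate] = _row_coords(row, 0, row.end - row.start + 1)
        node = SequenceNode(
            block.block_id,
            ungap(block.row_for(first).gapped_seq),
            {r.isolate for r in block.rows},
            coords,
        )
        graph.add_node(node, validate=False)
    for isolate in order:
        placed = sorted(
            (n.abs_interval(isolate)[0], n.name) for n in graph.nodes_for_isolate(isolate)
        )
        for (_, prev), (_, nxt) in zip(placed, placed[1:]):
            graph.add_edge(prev, nxt, {isolate})
    return graph


def collapse_block(
    block: AlignedBlock,
    offsets: Optional[Mapping[str, Tuple[int, int, str]]] = None,
    isolate_order: Optional[Sequence[str]] = None,
) -> GenomeGraph:
    """Collapse a gapped block alignment into a subgraph.

    Columns are partitioned by character among non-gap rows; maximal runs of
    columns with identical partitions each emit one node per character group.
    Nodes are named ``<block_id>_<n>`` sequentially in column order (within a
    column run, the group containing the lexicographically smallest isolate
    comes first); a block that collapses to a single node keeps the block
    name.  Per-isolate coordinates come from each row's genomic offset plus a
    cursor of consumed bases; '-' strand rows receive negative, reversed
    coordinates.  Every row's path through the subgraph spells its ungapped
    sequence.
    """
    block.validate()
    rows = block.rows
    if offsets is not None:
        rows = []
        for row in block.rows:
            if row.isolate not in offsets:
                raise BuildError(f"no genomic offset for row {row.isolate!r}")
            start, end, strand = offsets[row.isolate]
            if end - start + 1 != len(row.ungapped()):
                raise BuildError(
                    f"offset span ({start}, {end}) does not match row "
                    f"{row.isolate!r} length {len(row.ungapped())}"
                )
            rows.append(AlignedRow(row.isolate, row.gapped_seq, start, end, strand))
    order = list(isolate_order or [r.isolate for r in rows])
    present_order = [i for i in order if i in {r.isolate for r in rows}]

    width = len(rows[0].gapped_seq)

    # per-column partition of row indices by character
    def grouping(col: int) -> Tuple[Tuple[int, ...], ...]:
        groups: Dict[str, List[int]] = {}
        for ri, row in enumerate(rows):
            c = row.gapped_seq[col]
            if c != GAP:
                groups.setdefault(c, []).append(ri)
        return tuple(sorted(tuple(g) for g in groups.values()))

    runs: List[Tuple[int, int, Tuple[Tuple[int, ...], ...]]] = []
    start_col = 0
    current = grouping(0)
    for col in range(1, width):
        g = grouping(col)
        if g != current:
            runs.append((start_col, col - 1, current))
            start_col, current = col, g
    runs.append((start_col, width - 1, current))

    n_total = sum(len(g) for _, _, g in runs)
    single = n_total == 1

    graph = GenomeGraph(isolates=present_order)
    cursors = {ri: 0 for ri in range(len(rows))}
    row_paths: Dict[int, List[str]] = {ri: [] for ri in range(len(rows))}
    counter = 1
    for c0, c1, groups in runs:
        length = c1 - c0 + 1
        ordered_groups = sorted(
            groups, key=lambda g: min(rows[ri].isolate for ri in g)
        )
        for group in ordered_groups:
            name = block.block_id if single else f"{block.block_id}_{counter}"
            counter += 1
            seq = rows[group[0]].gapped_seq[c0 : c1 + 1]
            coords = {}
            for ri in group:
                coords[rows[ri].isolate] = _row_coords(rows[ri], cursors[ri], length)
                row_paths[ri].append(name)
            node = SequenceNode(name, seq, {rows[ri].isolate for ri in group}, coords)
            # canonical orientation: first member isolate stored forward
            first = next(i for i in present_order if i in node.ids)
            if node.coords[first][0] < 0:
                node = node.flipped()
            graph.add_node(node)
        for group in groups:
            for ri in group:
                cursors[ri] += length
    for ri, row in enumerate(rows):
        path = row_paths[ri]
        if row.strand == "-":
            path = list(reversed(path))  # genomic order for the inverted row
        for prev, nxt in zip(path, path[1:]):
            graph.add_edge(prev, nxt, {row.isolate})
    return graph


def splice_subgraph(graph: GenomeGraph, temp_node_name: str, sub: GenomeGraph) -> GenomeGraph:
    """Replace the temporary node ``temp_node_name`` with subgraph ``sub``.

    Incoming edges are rewired, per isolate, to that isolate's first node of
    the subgraph (by forward-strand position) and outgoing edges to its last.
    """
    temp = graph.node(temp_node_name)
    sub_isolates = set()
    for n in sub.nodes():
        sub_isolates |= n.ids
    if sub_isolates != temp.ids:
        raise SpliceError(
            f"splice of {temp_node_name!r}: subgraph isolates {sorted(sub_isolates)} "
            f"!= temporary node ids {sorted(temp.ids)}"
        )
    for isolate in temp.ids:
        lo = min(n.abs_interval(isolate)[0] for n in sub.nodes_for_isolate(isolate))
        hi = max(n.abs_interval(isolate)[1] for n in sub.nodes_for_isolate(isolate))
        if (lo, hi) != temp.abs_interval(isolate):
            raise SpliceError(
                f"splice of {temp_node_name!r}: isolate {isolate!r} span ({lo}, {hi}) "
                f"!= temporary node span {temp.abs_interval(isolate)}"
            )

    if sub.n_nodes == 1 and temp_node_name in sub:
        # identity splice: the block collapsed to a single node with the
        # temporary node's own name; just swap the payload in place
        graph._nx.nodes[temp_node_name]["node"] = sub.node(temp_node_name)
        return graph

    first: Dict[str, str] = {}
    last: Dict[str, str] = {}
    for isolate in temp.ids:
        members = sub.nodes_for_isolate(isolate)
        first[isolate] = min(members, key=lambda n: n.abs_interval(isolate)[0]).name
        last[isolate] = max(members, key=lambda n: n.abs_interval(isolate)[1]).name

    incoming = [(u, set(ids)) for u, v, ids in graph.edges() if v == temp_node_name]
    outgoing = [(v, set(ids)) for u, v, ids in graph.edges() if u == temp_node_name]
    graph.remove_node(temp_node_name)
    for node in sub.nodes():
        graph.add_node(SequenceNode(node.name, node.sequence, set(node.ids), dict(node.coords)))
    for u, v, ids in sub.edges():
        graph.add_edge(u, v, set(ids))
    for u, ids in incoming:
        for isolate in ids:
            graph.add_edge(u, first[isolate], {isolate})
    for v, ids in outgoing:
        for isolate in ids:
            graph.add_edge(last[isolate], v, {isolate})
    return graph


def _realign_block(
    block: AlignedBlock,
    aligner: str,
    scoring: Optional[Mapping[str, float]],
) -> AlignedBlock:
    """Realign a block's ungapped rows (in block orientation), keeping the
    original genomic offsets and strands."""
    seqs = {row.isolate: row.ungapped() for row in block.rows}
    if aligner == "builtin":
        aligned = progressive_msa(seqs, scoring, block_id=block.block_id)
    else:
        aligned = run_external_aligner(aligner, seqs)
    rows = []
    for row in block.rows:
        rows.append(
            AlignedRow(
                row.isolate,
                aligned.row_for(row.isolate).gapped_seq,
                row.start,
                row.end,
                row.strand,
            )
        )
    out = AlignedBlock(block.block_id, rows)
    out.validate()
    return out


def build_genome_graph(
    genomes: Mapping[str, str],
    xmfa: Optional[str] = None,
    decomposition: Optional[BlockDecomposition] = None,
    aligner: str = "builtin",
    scoring: Optional[Mapping[str, float]] = None,
    realign: Optional[bool] = None,
    metadata: Optional[Mapping[str, str]] = None,
) -> GenomeGraph:
    """Build a genome graph from ``{isolate: sequence}``.

    The co-linear block decomposition comes from a whole-genome aligner
    (``xmfa`` path), is passed directly (``decomposition``), or — with
    neither — the genomes are assumed rearrangement free and form a single
    block aligned with ``aligner`` (``"builtin"``, ``"mafft"``, ``"muscle"``
    or ``"clustalo"``).  ``realign`` controls whether multi-isolate blocks
    of a supplied decomposition are realigned (default: trust its gapping);
    colinear mode always aligns.  The returned graph is fully validated,
    including byte-identical reconstruction of every input genome.
    """
    if not genomes:
        raise BuildError("at least one genome is required")
    isolates = list(genomes)
    genomes = {i: genomes[i].upper() for i in isolates}
    for isolate, seq in genomes.items():
        if not seq:
            raise BuildError(f"genome {isolate!r} is empty")

    if xmfa is not None and decomposition is not None:
        raise BuildError("pass either xmfa or decomposition, not both")
    if xmfa is not None:
        decomp = parse_xmfa(xmfa, isolates, genomes)
        do_realign = bool(realign)
        mode = "xmfa"
    elif decomposition is not None:
        decomp = decomposition
        do_realign = bool(realign)
        mode = "decomposition"
    else:
        if len(isolates) == 1:
            block = AlignedBlock(
                "Aln_1",
                [AlignedRow(isolates[0], genomes[isolates[0]], 1, len(genomes[isolates[0]]), "+")],
            )
        elif aligner == "builtin":
            block = progressive_msa(genomes, scoring)
        else:
            block = run_external_aligner(aligner, genomes)
        decomp = BlockDecomposition([block], {i: len(genomes[i]) for i in isolates})
        do_realign = False  # just aligned
        mode = "colinear"

    graph = build_structure_graph(decomp, isolates)
    for block in decomp.blocks:
        if len(block.rows) < 2:
            continue  # single-isolate blocks pass through as final nodes
        block = normalize_block(block, isolates)
        if do_realign:
            block = _realign_block(block, aligner, scoring)
        sub = collapse_block(block, isolate_order=isolates)
        splice_subgraph(graph, block.block_id, sub)

    graph.metadata.update(
        {
            "mode": mode,
            "aligner": aligner if (mode == "colinear" or do_realign) else "none",
            "scoring": repr(dict(scoring)) if scoring else "default",
            "builder": f"seqgraph {_version}",
        }
    )
    if metadata:
        graph.metadata.update(metadata)

    graph.validate()
    for isolate in isolates:
        rebuilt = graph.reconstruct_sequence(isolate)
        if rebuilt != genomes[isolate]:
            raise BuildError(
                f"round-trip failure: reconstruction of {isolate!r} does not match "
                f"its input genome"
            )
    return graph
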