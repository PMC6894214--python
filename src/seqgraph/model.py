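"""Genome-graph data model.

A genome graph is a directed sequence graph in which every node carries a
sub-sequence that is homologous across the isolates listed in its ``ids``
attribute, and each isolate's genome is a labelled walk through the graph.
Per-isolate 1-based inclusive coordinates (``leftend``, ``rightend``) record
where the node's sequence sits on that isolate's forward strand.  A segment
carried in inverted orientation by an isolate is stored with *negative,
reversed* coordinates: a node occupying forward-strand positions ``[s, e]``
in inverted orientation stores ``leftend = -e, rightend = -s``, and the
isolate's sequence is recovered by reverse-complementing the node sequence.

Node sequences are stored in the orientation of the first member isolate
(by the graph's isolate order), which therefore always has positive
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

from ._seq import NUCLEOTIDES, revcomp

Orientation = str  # "+" or "-"


class GraphError(Exception):
    """Base class for genome-graph errors."""


class ValidationError(GraphError):
    """An invariant of the data model is violated."""


class WalkError(GraphError):
    """An isolate's labelled walk is broken (missing edge, gap or overlap)."""


@dataclass
class SequenceNode:
    """One node of the genome graph.

    Parameters
    ----------
    name : unique node identifier, e.g. ``"Aln_66_3"``.
    sequence : uppercase nucleotide string (IUPAC, no gaps), length >= 1.
    ids : isolates whose genomes traverse this node.
    coords : per-isolate ``(leftend, rightend)``; negative and reversed for
        inverted occurrences.
    """

    name: str
    sequence: str
    ids: Set[str] = field(default_factory=set)
    coords: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.ids = set(self.ids)
        self.coords = {i: (int(l), int(r)) for i, (l, r) in self.coords.items()}

    # -- coordinate helpers -------------------------------------------------

    def is_inverted(self, isolate: str) -> bool:
        """True if ``isolate`` carries this node in inverted orientation."""
        return self.coords[isolate][0] < 0

    def abs_interval(self, isolate: str) -> Tuple[int, int]:
        """Forward-strand interval ``(lo, hi)`` of this node for ``isolate``."""
        l, r = self.coords[isolate]
        return (min(abs(l), abs(r)), max(abs(l), abs(r)))

    def forward_segment(self, isolate: str) -> str:
        """The forward-strand sequence this node contributes to ``isolate``."""
        return revcomp(self.sequence) if self.is_inverted(isolate) else self.sequence

    def __len__(self) -> int:
        return len(self.sequence)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("node name must be non-empty")
        if not self.sequence:
            raise ValidationError(f"node {self.name!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"node {self.name!r}: invalid sequence characters {sorted(bad)}"
            )
        if not self.ids:
            raise ValidationError(f"node {self.name!r}: ids must be non-empty")
        if set(self.coords) != self.ids:
            raise ValidationError(
                f"node {self.name!r}: coords keys {sorted(self.coords)} != ids {sorted(self.ids)}"
            )
        n = len(self.sequence)
        for iso, (l, r) in self.coords.items():
            if l > 0 and r > 0:
                if not (1 <= l <= r):
                    raise ValidationError(
                        f"node {self.name!r}, isolate {iso!r}: forward coords require "
                        f"1 <= leftend <= rightend, got ({l}, {r})"
                    )
                if r - l + 1 != n:
                    raise ValidationError(
                        f"node {self.name!r}, isolate {iso!r}: span {r - l + 1} != "
                        f"sequence length {n}"
                    )
            elif l < 0 and r < 0:
                if abs(l) < abs(r):
                    raise ValidationError(
                        f"node {self.name!r}, isolate {iso!r}: inverted coords require "
                        f"|leftend| >= |rightend|, got ({l}, {r})"
                    )
                if abs(l) - abs(r) + 1 != n:
                    raise ValidationError(
                        f"node {self.name!r}, isolate {iso!r}: inverted span "
                        f"{abs(l) - abs(r) + 1} != sequence length {n}"
                    )
            else:
                raise ValidationError(
                    f"node {self.name!r}, isolate {iso!r}: coords must be both positive "
                    f"(forward) or both negative (inverted), got ({l}, {r})"
                )

    def flipped(self) -> "SequenceNode":
        """The same node stored in the opposite orientation.

        Reverse-complements the sequence and swaps/negates every isolate's
        coordinate pair, so forward occurrences become inverted and vice
        versa.  Applying twice returns an equal node.
        """
        return SequenceNode(
            name=self.name,
            sequence=revcomp(self.sequence),
            ids=set(self.ids),
            coords={i: (-r, -l) for i, (l, r) in self.coords.items()},
        )


def edge_name(source: str, target: str) -> str:
    """Canonical edge name: ``"<source> (-) <target>"``."""
    return f"{source} (-) {target}"


class GenomeGraph:
    """Directed sequence graph with labelled genome walks.

    Backed by a :class:`networkx.DiGraph`; node payloads are
    :class:`SequenceNode` objects, edges carry an ``ids`` set.
    """

    def __init__(
        self,
        isolates: Iterable[str] = (),
        metadata: Optional[Dict[str, str]] = None,
    ) -> None:
        self.isolates: List[str] = list(isolates)
        self.metadata: Dict[str, str] = dict(metadata or {})
        self._nx = nx.DiGraph()

    # -- basic container protocol -------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._nx.number_of_edges()

    def __contains__(self, name: str) -> bool:
        return name in self._nx

    def __iter__(self) -> Iterator[str]:
        return iter(self._nx)

    def node_names(self) -> List[str]:
        return list(self._nx)

    def node(self, name: str) -> SequenceNode:
        try:
            return self._nx.nodes[name]["node"]
        except KeyError:
            raise GraphError(f"no node named {name!r}") from None

    def nodes(self) -> Iterator[SequenceNode]:
        for name in self._nx:
            yield self._nx.nodes[name]["node"]

    def edges(self) -> Iterator[Tuple[str, str, Set[str]]]:
        for u, v, data in self._nx.edges(data=True):
            yield u, v, data["ids"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._nx.has_edge(u, v)

    def edge_ids(self, u: str, v: str) -> Set[str]:
        try:
            return self._nx.edges[u, v]["ids"]
        except KeyError:
            raise GraphError(f"no edge {edge_name(u, v)!r}") from None

    def predecessors(self, name: str) -> List[str]:
        return list(self._nx.predecessors(name))

    def successors(self, name: str) -> List[str]:
        return list(self._nx.successors(name))

    # -- mutation ------------------------------------------------------------

    def add_node(self, node: SequenceNode, validate: bool = True) -> "GenomeGraph":
        """Add ``node``; raises :class:`ValidationError` on duplicates or
        invariant violations.  ``validate=False`` admits temporary structural
        nodes whose representative sequence does not yet satisfy per-isolate
        span invariants."""
        if node.name in self._nx:
            raise ValidationError(f"duplicate node name {node.name!r}")
        if validate:
            node.validate()
            unknown = node.ids - set(self.isolates)
            if unknown:
                raise ValidationError(
                    f"node {node.name!r}: unknown isolates {sorted(unknown)}"
                )
        self._nx.add_node(node.name, node=node)
        return self

    def remove_node(self, name: str) -> None:
        if name not in self._nx:
            raise GraphError(f"no node named {name!r}")
        self._nx.remove_node(name)

    def add_edge(self, u: str, v: str, ids: Iterable[str]) -> None:
        """Add (or merge ids into) the directed edge ``u -> v``."""
        ids = set(ids)
        if u == v:
            raise ValidationError(f"self-loop on node {u!r} is not allowed")
        if u not in self._nx or v not in self._nx:
            missing = u if u not in self._nx else v
            raise GraphError(f"edge endpoint {missing!r} not in graph")
        if not ids:
            raise ValidationError(f"edge {edge_name(u, v)!r}: ids must be non-empty")
        allowed = self.node(u).ids & self.node(v).ids
        if not ids <= allowed:
            raise ValidationError(
                f"edge {edge_name(u, v)!r}: ids {sorted(ids - allowed)} not shared by "
                f"both endpoints"
            )
        if self._nx.has_edge(u, v):
            self._nx.edges[u, v]["ids"] |= ids
        else:
            self._nx.add_edge(u, v, ids=ids, name=edge_name(u, v))

    # -- walks and reconstruction ---------------------------------------------

    def nodes_for_isolate(self, isolate: str) -> List[SequenceNode]:
        return [n for n in self.nodes() if isolate in n.ids]

    def genome_length(self, isolate: str) -> int:
        """Genome length inferred from the maximal forward-strand coordinate."""
        nodes = self.nodes_for_isolate(isolate)
        if not nodes:
            raise GraphError(f"isolate {isolate!r} not present in any node")
        return max(n.abs_interval(isolate)[1] for n in nodes)

    def isolate_walk(self, isolate: str) -> List[Tuple[str, Orientation]]:
        """The ordered walk of ``isolate`` through the graph.

        Nodes are ordered by ascending forward-strand position; orientation
        is ``"+"`` for forward and ``"-"`` for inverted traversal.  Raises
        :class:`WalkError` at the first coordinate gap/overlap or missing
        labelled edge.
        """
        if isolate not in self.isolates:
            raise GraphError(f"unknown isolate {isolate!r}")
        nodes = sorted(self.nodes_for_isolate(isolate), key=lambda n: n.abs_interval(isolate)[0])
        if not nodes:
            raise GraphError(f"isolate {isolate!r} not present in any node")
        for prev, nxt in zip(nodes, nodes[1:]):
            _, prev_hi = prev.abs_interval(isolate)
            nxt_lo, _ = nxt.abs_interval(isolate)
            if nxt_lo != prev_hi + 1:
                kind = "overlap" if nxt_lo <= prev_hi else "gap"
                raise WalkError(
                    f"isolate {isolate!r}: coordinate {kind} between nodes "
                    f"{prev.name!r} (ends {prev_hi}) and {nxt.name!r} (starts {nxt_lo})"
                )
            if not (self.has_edge(prev.name, nxt.name) and isolate in self.edge_ids(prev.name, nxt.name)):
                raise WalkError(
                    f"isolate {isolate!r}: no edge labelled with it between "
                    f"{prev.name!r} and {nxt.name!r}"
                )
        return [(n.name, "-" if n.is_inverted(isolate) else "+") for n in nodes]

    def reconstruct_sequence(self, isolate: str) -> str:
        """Rebuild ``isolate``'s genome by concatenating its walk.

        Forward nodes contribute their sequence as stored; inverted nodes are
        reverse-complemented.
        """
        walk = self.isolate_walk(isolate)
        return "".join(self.node(name).forward_segment(isolate) for name, _ in walk)

    # -- whole-graph validation ------------------------------------------------

    def validate(self) -> None:
        """Check every model invariant; raises on the first violation."""
        for node in self.nodes():
            node.validate()
            unknown = node.ids - set(self.isolates)
            if unknown:
                raise ValidationError(
                    f"node {node.name!r}: unknown isolates {sorted(unknown)}"
                )
        for u, v, ids in self.edges():
            if not ids:
                raise ValidationError(f"edge {edge_name(u, v)!r}: empty ids")
            if not ids <= (self.node(u).ids & self.node(v).ids):
                raise ValidationError(
                    f"edge {edge_name(u, v)!r}: ids not a subset of endpoint ids"
                )
        for isolate in self.isolates:
            nodes = self.nodes_for_isolate(isolate)
            if not nodes:
                continue
            first = min(n.abs_interval(isolate)[0] for n in nodes)
            if first != 1:
                raise ValidationError(
                    f"isolate {isolate!r}: walk starts at {first}, expected 1"
                )
            self.isolate_walk(isolate)  # raises WalkError on gap/overlap/missing edge

    # -- misc -------------------------------------------------------------------

    def copy(self) -> "GenomeGraph":
        out = GenomeGraph(self.isolates, self.metadata)
        for node in self.nodes():
            out._nx.add_node(node.name, node=SequenceNode(
                node.name, node.sequence, set(node.ids), dict(node.coords)))
        for u, v, ids in self.edges():
            out._nx.add_edge(u, v, ids=set(ids), name=edge_name(u, v))
        return out

    def subgraph(self, names: Iterable[str]) -> "GenomeGraph":
        """Induced subgraph on ``names`` (deep copies of nodes and edges)."""
        names = set(names)
        out = GenomeGraph(self.isolates, dict(self.metadata))
        for name in names:
            n = self.node(name)
            out._nx.add_node(name, node=SequenceNode(n.name, n.sequence, set(n.ids), dict(n.coords)))
        for u, v, ids in self.edges():
            if u in names and v in names:
                out._nx.add_edge(u, v, ids=set(ids), name=edge_name(u, v))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeGraph):
            return NotImplemented
        if self.isolates != other.isolates or self.metadata != other.metadata:
            return False
        if set(self.node_names()) != set(other.node_names()):
            return False
        for name in self.node_names():
            a, b = self.node(name), other.node(name)
            if (a.sequence, a.ids, a.coords) != (b.sequence, b.ids, b.coords):
                return False
        mine = {(u, v): ids for u, v, ids in self.edges()}
        theirs = {(u, v): ids for u, v, ids in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:
        return (
            f"GenomeGraph(isolates={self.isolates!r}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


def add_node(graph: GenomeGraph, node: SequenceNode) -> GenomeGraph:
    """Functional wrapper around :meth:`GenomeGraph.add_node`."""
    return graph.add_node(node)


def isolate_walk(graph: GenomeGraph, isolate: str) -> List[Tuple[str, Orientation]]:
    return graph.isolate_walk(isolate)


def reconstruct_sequence(graph: GenomeGraph, isolate: str) -> str:
    return graph.reconstruct_sequence(isolate)
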