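"""GraphML / pickle serialization, FASTA output and the build report.

GraphML is the primary interchange format: node attributes are flattened to
the ``name`` / ``sequence`` / ``ids`` (comma-separated) / ``<isolate>_leftend``
/ ``<isolate>_rightend`` scheme that generic graph viewers expect, so the
files load directly into Cytoscape or any GraphML consumer.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Dict

import networkx as nx

from ._seq import write_fasta
from .model import GenomeGraph, GraphError, SequenceNode, edge_name


class SchemaError(GraphError):
    """A serialized graph violates the attribute schema."""


_META_PREFIX = "meta_"


def to_networkx(graph: GenomeGraph) -> nx.DiGraph:
    """Flatten a :class:`GenomeGraph` into an attribute-typed DiGraph."""
    g = nx.DiGraph()
    g.graph["isolates"] = ",".join(graph.isolates)
    for key, value in graph.metadata.items():
        g.graph[_META_PREFIX + key] = str(value)
    seq_len = graph.metadata.get("seq_len_attr") == "1"
    for node in graph.nodes():
        attrs = {
            "name": node.name,
            "sequence": node.sequence,
            "ids": ",".join(sorted(node.ids)),
        }
        for isolate, (l, r) in node.coords.items():
            attrs[f"{isolate}_leftend"] = int(l)
            attrs[f"{isolate}_rightend"] = int(r)
        if seq_len:
            attrs["seq_len"] = len(node.sequence)
        g.add_node(node.name, **attrs)
    for u, v, ids in graph.edges():
        g.add_edge(u, v, name=edge_name(u, v), ids=",".join(sorted(ids)))
    return g


def export_graphml(graph: GenomeGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), str(path))


def import_graphml(path) -> GenomeGraph:
    """Load a GraphML genome graph, checking the attribute schema.

    Raises :class:`SchemaError` naming the offending node when a required
    attribute (sequence, ids, or a member isolate's coordinate pair) is
    missing.
    """
    try:
        g = nx.read_graphml(str(path), node_type=str)
    except Exception as exc:
        raise SchemaError(f"cannot read GraphML file {path}: {exc}") from exc
    isolates = [i for i in g.graph.get("isolates", "").split(",") if i]
    metadata = {
        key[len(_META_PREFIX):]: str(value)
        for key, value in g.graph.items()
        if key.startswith(_META_PREFIX)
    }
    out = GenomeGraph(isolates, metadata)
    for name, data in g.nodes(data=True):
        for required in ("sequence", "ids"):
            if required not in data:
                raise SchemaError(f"node {name!r}: missing attribute {required!r}")
        ids = {i for i in str(data["ids"]).split(",") if i}
        coords = {}
        for isolate in ids:
            for side in ("leftend", "rightend"):
                if f"{isolate}_{side}" not in data:
                    raise SchemaError(
                        f"node {name!r}: missing attribute '{isolate}_{side}'"
                    )
            coords[isolate] = (
                int(data[f"{isolate}_leftend"]),
                int(data[f"{isolate}_rightend"]),
            )
        out.add_node(SequenceNode(name, str(data["sequence"]), ids, coords))
    for u, v, data in g.edges(data=True):
        if "ids" not in data:
            raise SchemaError(f"edge {edge_name(u, v)!r}: missing attribute 'ids'")
        out.add_edge(u, v, {i for i in str(data["ids"]).split(",") if i})
    return out


def save_graph(graph: GenomeGraph, path) -> None:
    """Serialize as a native Python object (pickle)."""
    with open(path, "wb") as handle:
        pickle.dump(graph, handle, protocol=pickle.HIGHEST_PROTOCOL)


def load_graph(path) -> GenomeGraph:
    with open(path, "rb") as handle:
        graph = pickle.load(handle)
    if not isinstance(graph, GenomeGraph):
        raise SchemaError(f"{path} does not contain a GenomeGraph")
    return graph


def export_fasta(graph: GenomeGraph, isolate: str, path, wrap: int = 70) -> None:
    """Write ``isolate``'s reconstructed genome as a single-record FASTA."""
    if isolate not in graph.isolates:
        raise GraphError(f"unknown isolate {isolate!r}")
    write_fasta(path, {isolate: graph.reconstruct_sequence(isolate)}, wrap=wrap)


@dataclass
class GraphReport:
    """Summary statistics of a genome graph.

    ``density`` uses the directed simple-graph formula
    ``n_edges / (n_nodes * (n_nodes - 1))``; average in- and out-degree both
    equal ``n_edges / n_nodes``.
    """

    n_nodes: int
    n_edges: int
    avg_in_degree: float
    avg_out_degree: float
    total_node_sequence_length: int
    density: float
    genome_lengths: Dict[str, int]

    def render(self) -> str:
        lines = [
            "Genome graph report",
            f"Number of nodes: {self.n_nodes}",
            f"Number of edges: {self.n_edges}",
            f"Average in degree: {self.avg_in_degree:.4f}",
            f"Average out degree: {self.avg_out_degree:.4f}",
            f"Total sequence length of nodes: {self.total_node_sequence_length}",
            f"Graph density: {self.density:.6f}",
            "Genome lengths:",
        ]
        lines += [f"  {isolate}: {length}" for isolate, length in self.genome_lengths.items()]
        return "\n".join(lines) + "\n"


def generate_report(graph: GenomeGraph) -> GraphReport:
    n, m = graph.n_nodes, graph.n_edges
    avg = m / n if n else 0.0
    density = m / (n * (n - 1)) if n >= 2 else 0.0
    lengths = {}
    for isolate in graph.isolates:
        if graph.nodes_for_isolate(isolate):
            lengths[isolate] = graph.genome_length(isolate)
    return GraphReport(
        n_nodes=n,
        n_edges=m,
        avg_in_degree=avg,
        avg_out_degree=avg,
        total_node_sequence_length=sum(len(node.sequence) for node in graph.nodes()),
        density=density,
        genome_lengths=lengths,
    )


def write_report(graph: GenomeGraph, path) -> GraphReport:
    report = generate_report(graph)
    with open(path, "w") as handle:
        handle.write(report.render())
    return report
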