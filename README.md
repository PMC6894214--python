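# seqgraph

Genome graphs for bacterial-scale comparative genomics, in Python.

A single linear reference genome biases everything downstream of it: genes
absent from the reference are invisible, rearrangements scramble coordinate
arithmetic, and every new isolate needs its own VCF against an arbitrary
anchor. `seqgraph` represents a set of related genomes as one **directed
sequence graph**: each node carries a sub-sequence that is homologous across
the isolates listed on it, and each genome is a labelled walk through the
graph whose concatenation reproduces the input sequence exactly.

The model prioritises biological interpretability over maximal compression:

- **Coordinates on every node.** Each node stores, per member isolate, the
  1-based inclusive positions of its first and last base
  (`<isolate>_leftend`, `<isolate>_rightend`). Given a single node you can
  say that its first `A` is position 132 in isolate A and 21,310 in
  isolate B — so ordinary GTF/GFF annotations work directly on the graph.
- **Inversions in one node.** A segment carried in reverse-complement
  orientation by some isolate stays in the *same* node, flagged by
  negative, reversed coordinates (`leftend = -e, rightend = -s` for a
  segment on forward positions `[s, e]`); reconstruction simply
  reverse-complements the node sequence for that isolate. Genes inside an
  inversion are therefore still shared between isolates, and the
  breakpoints live on the flanking edges.
- **No self-loops.** Tandem repeats are represented as an explicit
  insertion node private to the isolates that carry the extra copies, so
  traversal code stays simple and every node keeps well-defined start/stop
  positions.

Construction is two-staged, mirroring how whole-genome aligners work:
co-linear blocks (from a progressiveMauve-style XMFA, or a single block for
rearrangement-free genomes) become temporary structural nodes; each block's
gapped multiple alignment is then *collapsed* — maximal runs of columns
with identical row partitions become shared nodes, branching at variant
columns — and the resulting subgraph is spliced in place of the temporary
node. After every build the master invariant is checked: each isolate's
walk reconstructs its input genome byte for byte.

On top of the graph: genome/sub-sequence/gene extraction, coordinate
liftover between isolates, largest conserved region, isolate-specific SNP
nodes, and a position-based (not similarity-based) gene-orthology matrix
that resolves high-identity paralogues by locus. Graphs serialize to
GraphML (loadable in Cytoscape, R or networkx) or pickle. A synthetic
genome-set generator with recorded mutation truth provides oracles for all
of it.

## Worked example

Two genomes identical except that `isoB` carries three extra tandem `ATG`
units:

```python
import seqgraph as sg

flank5 = "ACCTGATTGCGTATCGATTA"
flank3 = "GGCTTACCGTAGGACCTAAG"
genomes = {
    "isoA": flank5 + "ATG" * 2 + flank3,
    "isoB": flank5 + "ATG" * 5 + flank3,
}
graph = sg.build_genome_graph(genomes)
for node in graph.nodes():
    print(node.name, node.sequence, sorted(node.ids), node.coords)
```

```
Aln_1_1 ACCTGATTGCGTATCGATTA ['isoA', 'isoB'] {'isoA': (1, 20), 'isoB': (1, 20)}
Aln_1_2 ATGATGATG ['isoB'] {'isoB': (21, 29)}
Aln_1_3 ATGATGGGCTTACCGTAGGACCTAAG ['isoA', 'isoB'] {'isoA': (21, 46), 'isoB': (30, 55)}
```

Three nodes: shared prefix, a 9 bp insertion node private to `isoB`, and
the shared remainder. `isoA`'s walk skips the insertion node
(`[('Aln_1_1', '+'), ('Aln_1_3', '+')]`), and
`graph.reconstruct_sequence("isoB")` returns `isoB`'s input exactly. The
build report prints:

```
Genome graph report
Number of nodes: 3
Number of edges: 3
Average in degree: 1.0000
Average out degree: 1.0000
Total sequence length of nodes: 55
Graph density: 0.500000
Genome lengths:
  isoA: 46
  isoB: 55
```

The same workflow from a shell, via the `seqgraph` console script:

```bash
seqgraph simulate --n-genomes 3 --length 10000 --seed 1 --out-dir fixtures/
seqgraph build --seq-file fixtures/manifest.tsv --xmfa fixtures/blocks.xmfa --out mygraph
seqgraph report --graph mygraph.graphml
seqgraph extract --graph mygraph.graphml --isolate iso2 --out iso2.fasta
seqgraph conserved --graph mygraph.graphml
```

See `docs/methods.md` for the model, algorithm and parameter details.

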