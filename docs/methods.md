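# Methods

## The graph model

A genome graph here is a simple directed graph `G = (V, E)` over a set of
isolates `I`. Every node `v` carries:

- `sequence(v)`: an uppercase nucleotide string (IUPAC letters, no gaps),
  stored in the orientation of the first member isolate by the graph's
  isolate order;
- `ids(v) ⊆ I`: the isolates whose genomes traverse the node;
- `coords(v, i) = (leftend, rightend)` for each `i ∈ ids(v)`: 1-based
  inclusive positions on isolate `i`'s forward strand.

A forward occurrence satisfies `1 ≤ leftend ≤ rightend` and
`rightend − leftend + 1 = |sequence|`. An inverted occurrence of the
segment occupying forward positions `[s, e]` stores `(−e, −s)` — negative
*and* reversed, so `|leftend| ≥ |rightend|` is a machine-checkable
inversion flag, and the isolate's sequence is recovered by
reverse-complementing the node sequence. Because node sequences are kept
in the orientation of their first member isolate, that isolate always has
positive coordinates; a collapse result that would violate this is flipped
(reverse-complement the sequence, map every `(l, r)` to `(−r, −l)`), an
involution that preserves all other invariants.

Edges are named `"<source> (-) <target>"` and labelled with the isolates
that traverse them; an edge's ids must be a subset of both endpoints' ids,
and self-loops are disallowed (repeats are explicit insertion nodes, not
cycles). For every isolate, the nodes containing it — ordered by
`min(|leftend|, |rightend|)` — must form a walk connected by edges
labelled with that isolate whose forward-strand intervals tile
`[1, genome_length]` without gap or overlap. The master invariant, checked
after every build, is that concatenating each walk (reverse-complementing
inverted nodes) reproduces the input genome byte for byte.

Each isolate traverses a node at most once (one coordinate pair per
isolate per node), so segmental duplications within one genome become
distinct nodes. `N` and other IUPAC ambiguity codes are literal characters
that only group with identical characters during collapse; no identity is
inferred.

## Construction

Building is two-staged:

1. **Structural graph.** The genomes are decomposed into co-linear blocks:
   either parsed from an XMFA file as emitted by whole-genome aligners
   (progressiveMauve dialect; sequence indices map to isolates via the
   input order, which is why the CLI takes an explicit manifest), or — in
   colinear mode — a single block holding a fresh multiple alignment of
   the whole genomes. Per-isolate coverage gaps between XMFA blocks are
   closed by synthesizing single-isolate blocks, because the tiling
   invariant (and hence round-trip correctness) outranks alignment
   coverage. Each block becomes one temporary node `Aln_<k>`, holding a
   representative sequence and per-row coordinates (negative for `-`
   strand rows); blocks adjacent on an isolate's genome are connected by
   edges labelled with it. Blocks are first normalised so that their first
   member isolate lies on the `+` strand.

2. **Collapse and splice.** Each multi-isolate block's gapped alignment is
   collapsed column-wise: rows with a gap are absent from a column, the
   remaining rows are partitioned by character, and maximal runs of
   consecutive columns with identical partitions each emit one node per
   group. Children are named `<block>_<n>` sequentially in column order
   (within a run, the group containing the lexicographically smallest
   isolate first); a block that collapses to a single node keeps the block
   name, since the numbering scheme describes *split* nodes. Per-row
   cursors of consumed bases plus the row's genomic offset give each
   node's coordinates; `-` strand rows receive negative, reversed pairs.
   Edges follow each row's nodes in that isolate's genomic order, so an
   inverted row's path runs counter to the alignment direction. The
   subgraph then replaces the temporary node: incoming edges are rewired,
   per isolate, to that isolate's first subgraph node and outgoing edges
   to its last. Single-isolate blocks pass through as final nodes —
   there is nothing to align.

Multi-isolate XMFA blocks are *optionally* realigned (`realign=True`) with
the configured aligner; by default the XMFA gapping is trusted, which is
deterministic and already a valid alignment. Colinear mode always aligns.
Any reconstruction mismatch aborts the build naming the offending isolate;
no graph is emitted.

## The built-in aligner

External MSA tools (mafft, muscle, clustalo) are the intended path for
hard alignments; wrappers invoke them over temporary FASTA files, check
that every output row ungaps to its input, and raise an explicit
"aligner unavailable" error when the executable is missing. The built-in
aligner exists so graphs can be built and tested without binaries:

- Pairwise: Needleman–Wunsch/Gotoh with affine gaps, a gap of length `L`
  scoring `gap_open + L·gap_extend`. Defaults: match `+1`, mismatch `−1`,
  gap_open `−2`, gap_extend `−0.5` — chosen to prefer one contiguous gap
  over scattered ones, matching the block-wise indel structure of closely
  related genomes. Insertion and deletion runs may abut (X↔Y transitions
  each pay their own open). Traceback ties prefer diagonal over up over
  left, so output is deterministic. The recurrence is vectorised per row
  with numpy (the within-row gap state via a running maximum), which keeps
  kilobase-scale alignments fast without extension modules.
- Progressive: sequences are added in input order, each aligned against
  the majority-character consensus (ties to the lexicographically smallest
  character) of the running profile; consensus gaps are propagated to all
  previous rows. Adequate for the highly similar within-block sequences
  this toolkit collapses; it makes no attempt at guide trees.

## Queries

- **Extraction** locates the covering nodes by binary search on the
  isolate's sorted intervals and splices forward-strand slices, without
  reconstructing the whole genome. Gene extraction reverse-complements
  `-` strand features.
- **Liftover** (`translate_position`) finds the node and stored-sequence
  index of the query base and reads the target isolate's coordinates at
  the same index; at an inverted occurrence the offset is reversed
  (`len − 1 − o`), so base-level homology is preserved. The result is
  negated when the two isolates carry the node in opposite orientations,
  and `None` when the base falls in sequence the target isolate lacks —
  positions are never interpolated.
- **Gene subgraphs** contain the nodes covering the feature on its own
  isolate, extended by the other isolates' nodes spanning the same region
  so alternative alleles are visible; a `seq_len` attribute is attached on
  export for node sizing in viewers. A single universal node means the
  gene is identical in all isolates.
- **Conserved regions**: the longest node whose ids equal the full isolate
  set (ties broken by name). Note an inverted-but-otherwise-identical
  segment is still conserved under this definition — inversion does not
  remove homology. The inverse query returns nodes strictly shorter than a
  threshold (default 3 bp) private to one isolate: isolate-specific SNPs.
- **Homology matrix**: each gene's footprint is the set of
  (node, stored-sequence interval) pairs it covers. Genes from two
  isolates match when their footprints share at least
  `overlap_threshold` (default 0.5) of the shorter footprint's length —
  robust to boundary indels while rejecting unrelated loci — with greedy
  1:1 assignment by descending shared length (ties by gene id). Matching
  is positional, not similarity-based, so high-identity paralogues at
  distinct loci resolve to their locus counterparts.

## Serialization and report

GraphML is the interchange format: node attributes `name`, `sequence`,
`ids` (comma-separated) and one `<isolate>_leftend`/`<isolate>_rightend`
integer pair per member isolate; edge attributes `name` and `ids`; graph
attributes carry the isolate order and build metadata. Import validates
the schema and names the offending node on failure. A pickle round-trip is
provided for in-process persistence. The report contains node and edge
counts, average in/out degree (`m/n` each), total node sequence length,
density — the directed simple-graph formula `m / (n(n−1))`, 0 for fewer
than two nodes — and per-isolate genome lengths.

## The synthetic generator

Fixtures are derived from a uniform-random root: isolate 1 *is* the root,
isolates 2..n are mutated independently. Events are substitutions
(per-base probability `sub_rate`, to a uniformly chosen different base),
insertions and deletions (binomial counts at `ins_rate`/`del_rate` per
base, geometric lengths with mean 3 — short indels dominate within
co-linear blocks), tandem-repeat expansions (random 3–6 bp unit, 1–3 extra
copies) and segmental inversions (length between ~L/20 and ~L/8, at least
20 bp). Defaults are 1 substitution per kb, one indel per 5 kb of each
flavour, and one inversion per fixture set. All of a genome's events are
mutually non-overlapping, and inversion intervals (±1 bp guard) are
excluded from *every* genome's other events, so inverted segments are
exact reverse-complements of root slices and block breakpoints are clean.

Every event is recorded; replaying the event list reproduces the derived
genome exactly, and a piecewise map links root to derived coordinates.
From the truth the generator emits a correct co-linear block decomposition
(root segments between inversion breakpoints; rows gapped on a
root-template with private insertion columns) and its XMFA rendering, so
construction is testable without any aligner. Same seed, byte-identical
fixtures; per-genome seeds are spawned from the master seed.

What the generator does *not* emulate: phylogenetically correlated
mutation (genomes share no derived variants — an upper bound for graph
growth), rearrangements other than inversion (no translocations or
large-scale duplications), rate heterogeneity along the genome, and
sequencing artefacts. Passing tests therefore demonstrate correctness of
the graph machinery on clean co-linear decompositions, not robustness to
noisy whole-genome alignments of real assemblies.

## Problem sizes and numerical choices

The test suite builds graphs from sets of up to ten 10 kb genomes (via
truth-derived decompositions) and up to ten 1 kb genomes through the
built-in aligner; the aligner is cross-checked against exhaustive
enumeration on 200 seeded pairs of length ≤ 8. These sizes exercise every
code path — multi-block splicing, inversions, insertion columns,
singleton gap blocks — while keeping the whole suite fast. Scores are
half-integers held in float64, compared exactly during traceback with a
1e-6 tolerance. Degenerate inputs: empty alignments are rejected; a
single genome yields a single-node graph; an empty graph exports and
reports cleanly (density 0).

## Known limitations

- Co-linear block detection is delegated: real rearranged assemblies need
  an external whole-genome aligner to produce the XMFA.
- The built-in progressive aligner is quadratic in sequence length and
  holds full DP matrices; use external tools beyond a few kb.
- One coordinate pair per isolate per node means a genome cannot traverse
  a node twice; shared repeats collapse only within, not across, loci.
- Homology matching needs annotations on each isolate; it maps gene ids,
  it does not discover genes.
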