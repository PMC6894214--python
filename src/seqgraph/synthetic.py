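"""Synthetic genome sets with recorded mutation ground truth.

The generator derives a set of related genomes from one random root by
applying substitutions, short indels, tandem-repeat expansions and segmental
inversions at stated rates.  Every event is recorded, the replayed event
list reproduces each derived genome exactly, and a piecewise coordinate map
links root and derived positions — so the generator doubles as the oracle
for graph construction, reconstruction, liftover and homology tests.  When
rearrangements are present it also emits a correct co-linear block
decomposition (XMFA), making graph construction testable without external
whole-genome aligners.

Genomes are mutated independently from the root (an upper-bound regime for
graph growth: shared ancestry would share variants and nodes).  Isolate 1 is
always the unmutated root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import revcomp, ungap, write_fasta
from .align import AlignedBlock, AlignedRow
from .build import BlockDecomposition

BASES = "ACGT"

#: Default per-genome mutation rates: roughly 1 substitution per kb and one
#: short indel per 5 kb, with a single inversion per fixture set — the
#: regime used throughout the test suite for 1-10 kb roots.
DEFAULT_RATES: Dict[str, float] = {
    "sub_rate": 0.001,
    "ins_rate": 0.0002,
    "del_rate": 0.0002,
    "inv_count": 1,
    "repeat_expansions": 0,
}

_GEOM_P = 1.0 / 3.0  # geometric indel lengths, mean 3


class SyntheticError(Exception):
    pass


@dataclass(frozen=True)
class MutationEvent:
    """One mutation, in root coordinates (1-based, inclusive).

    kinds and payloads:
      - ``substitution``: ``root_start == root_end``, payload = new base
      - ``insertion``: payload inserted after position ``root_start``
        (``root_start == root_end``; 0 means before the first base)
      - ``deletion``: ``[root_start, root_end]`` removed
      - ``tandem_expansion``: payload = extra copy count of the unit
        ``root[root_start..root_end]``, inserted after the unit
      - ``inversion``: ``[root_start, root_end]`` reverse-complemented
    """

    kind: str
    root_start: int
    root_end: int
    payload: object = None


@dataclass(frozen=True)
class Piece:
    """One contiguous piece of a derived genome.

    ``kind == "root"`` pieces map back to the root interval
    ``[root_start, root_end]`` (on ``strand``); ``kind == "ins"`` pieces are
    inserted sequence anchored after root position ``root_start``.
    """

    derived_start: int
    derived_end: int
    kind: str
    root_start: int
    root_end: int
    strand: str
    seq: str


def apply_events(root: str, events: Sequence[MutationEvent]) -> Tuple[str, List[Piece]]:
    """Replay ``events`` (which must be mutually non-overlapping) on ``root``.

    Returns the derived genome and its piece decomposition.
    """
    events = sorted(events, key=lambda e: (e.root_start, e.root_end))
    for prev, nxt in zip(events, events[1:]):
        if nxt.root_start <= prev.root_end:
            raise SyntheticError(
                f"overlapping events at root positions {prev.root_start}-{prev.root_end} "
                f"and {nxt.root_start}-{nxt.root_end}"
            )
    pieces: List[Piece] = []
    out: List[str] = []
    d = 1

    def emit(seq: str, kind: str, rs: int, re_: int, strand: str) -> None:
        nonlocal d
        if not seq:
            return
        pieces.append(Piece(d, d + len(seq) - 1, kind, rs, re_, strand, seq))
        out.append(seq)
        d += len(seq)

    def emit_plain(a: int, b: int) -> None:
        if a <= b:
            emit(root[a - 1 : b], "root", a, b, "+")

    cur = 1
    for ev in events:
        if ev.kind == "substitution":
            emit_plain(cur, ev.root_start - 1)
            emit(str(ev.payload), "root", ev.root_start, ev.root_end, "+")
            cur = ev.root_end + 1
        elif ev.kind == "deletion":
            emit_plain(cur, ev.root_start - 1)
            cur = ev.root_end + 1
        elif ev.kind == "insertion":
            emit_plain(cur, ev.root_start)
            emit(str(ev.payload), "ins", ev.root_start, ev.root_start, "+")
            cur = ev.root_start + 1
        elif ev.kind == "tandem_expansion":
            emit_plain(cur, ev.root_end)
            unit = root[ev.root_start - 1 : ev.root_end]
            emit(unit * int(ev.payload), "ins", ev.root_end, ev.root_end, "+")
            cur = ev.root_end + 1
        elif ev.kind == "inversion":
            emit_plain(cur, ev.root_start - 1)
            emit(
                revcomp(root[ev.root_start - 1 : ev.root_end]),
                "root",
                ev.root_start,
                ev.root_end,
                "-",
            )
            cur = ev.root_end + 1
        else:
            raise SyntheticError(f"unknown event kind {ev.kind!r}")
    emit_plain(cur, len(root))
    return "".join(out), pieces


@dataclass
class MutationTruth:
    """Recorded ground truth for one derived genome."""

    events: List[MutationEvent]
    root_length: int
    derived_length: int
    pieces: List[Piece]

    def root_to_derived(self, pos: int) -> Optional[int]:
        """Derived position of root position ``pos`` (1-based), or ``None``
        if the base was deleted."""
        if not (1 <= pos <= self.root_length):
            raise SyntheticError(f"root position {pos} out of range")
        for piece in self.pieces:
            if piece.kind == "root" and piece.root_start <= pos <= piece.root_end:
                if piece.strand == "+":
                    return piece.derived_start + (pos - piece.root_start)
                return piece.derived_start + (piece.root_end - pos)
        return None

    def substitution_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "substitution")

    def inversions(self) -> List[MutationEvent]:
        return [e for e in self.events if e.kind == "inversion"]


def random_genome(length: int, rng: np.random.Generator) -> str:
    if length < 1:
        raise SyntheticError("genome length must be >= 1")
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _resolve_rates(rates: Optional[Mapping[str, float]]) -> Dict[str, float]:
    out = dict(DEFAULT_RATES)
    if rates is not None:
        unknown = set(rates) - set(DEFAULT_RATES)
        if unknown:
            raise SyntheticError(f"unknown rate keys {sorted(unknown)}")
        out.update(rates)
    for key, value in out.items():
        if value < 0:
            raise SyntheticError(f"rate {key!r} must be >= 0, got {value}")
    return out


def mutate_genome(
    root: str,
    rates: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    forced_events: Sequence[MutationEvent] = (),
    forbidden: Sequence[Tuple[int, int]] = (),
) -> Tuple[str, MutationTruth]:
    """Derive one mutated genome from ``root`` with recorded truth.

    Substitutions are drawn per base with probability ``sub_rate`` (to a
    uniformly chosen different base); insertion/deletion counts are binomial
    in the genome length with geometric lengths (mean 3); ``inv_count``
    segmental inversions and ``repeat_expansions`` tandem expansions are
    placed uniformly.  All events are mutually non-overlapping and avoid the
    ``forbidden`` root intervals; ``forced_events`` are accepted as given.
    """
    rates = _resolve_rates(rates)
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(root)
    occupied: List[Tuple[int, int]] = [
        (e.root_start, e.root_end) for e in forced_events
    ] + [tuple(iv) for iv in forbidden]
    events: List[MutationEvent] = list(forced_events)

    def free(s: int, e: int) -> bool:
        return all(e < a or s > b for a, b in occupied)

    def place(what: str, sampler) -> None:
        for _ in range(200):
            ev = sampler()
            if ev is not None and free(ev.root_start, ev.root_end):
                events.append(ev)
                occupied.append((ev.root_start, ev.root_end))
                return
        raise SyntheticError(
            f"could not place {what}: rates imply overlap exhaustion on a {L} bp root"
        )

    inv_lo = max(20, L // 20)
    inv_hi = max(inv_lo + 10, L // 8)
    for _ in range(int(rates["inv_count"])):
        def sample_inv() -> Optional[MutationEvent]:
            length = int(rng.integers(inv_lo, inv_hi + 1))
            if length + 2 > L:
                return None
            s = int(rng.integers(2, L - length + 1))
            return MutationEvent("inversion", s, s + length - 1)

        place("inversion", sample_inv)

    for _ in range(int(rates["repeat_expansions"])):
        def sample_rep() -> Optional[MutationEvent]:
            unit = int(rng.integers(3, 7))
            if unit > L:
                return None
            s = int(rng.integers(1, L - unit + 2))
            copies = int(rng.integers(1, 4))
            return MutationEvent("tandem_expansion", s, s + unit - 1, copies)

        place("tandem expansion", sample_rep)

    for _ in range(int(rng.binomial(L, rates["del_rate"]))):
        def sample_del() -> Optional[MutationEvent]:
            length = int(rng.geometric(_GEOM_P))
            if length >= L:
                return None
            s = int(rng.integers(1, L - length + 2))
            return MutationEvent("deletion", s, s + length - 1)

        place("deletion", sample_del)

    for _ in range(int(rng.binomial(L, rates["ins_rate"]))):
        def sample_ins() -> Optional[MutationEvent]:
            length = int(rng.geometric(_GEOM_P))
            anchor = int(rng.integers(0, L + 1))
            payload = random_genome(length, rng)
            return MutationEvent("insertion", anchor, anchor, payload)

        place("insertion", sample_ins)

    if rates["sub_rate"] > 0:
        mask = rng.random(L) < rates["sub_rate"]
        for p in (np.nonzero(mask)[0] + 1).tolist():
            if not free(p, p):
                continue
            choices = [b for b in BASES if b != root[p - 1]]
            new = choices[int(rng.integers(len(choices)))]
            events.append(MutationEvent("substitution", p, p, new))
            occupied.append((p, p))

    derived, pieces = apply_events(root, events)
    truth = MutationTruth(
        sorted(events, key=lambda e: (e.root_start, e.root_end)),
        L,
        len(derived),
        pieces,
    )
    return derived, truth


# -- fixture sets -------------------------------------------------------------


@dataclass
class FixtureSet:
    """A root genome plus independently mutated isolates with full truth.

    Isolate 1 is the unmutated root.  ``decomposition()`` derives a correct
    co-linear block decomposition (one block per root segment between
    inversion breakpoints) whose gapped rows come from the recorded events,
    so graphs can be built without any aligner.
    """

    names: List[str]
    root: str
    genomes: Dict[str, str]
    truths: Dict[str, MutationTruth]

    @property
    def genome_lengths(self) -> Dict[str, int]:
        return {iso: len(seq) for iso, seq in self.genomes.items()}

    def all_inversions(self) -> List[Tuple[str, MutationEvent]]:
        return [
            (iso, ev)
            for iso in self.names
            for ev in self.truths[iso].inversions()
        ]

    def decomposition(self) -> BlockDecomposition:
        L = len(self.root)
        cuts = {1, L + 1}
        for _, ev in self.all_inversions():
            cuts.add(ev.root_start)
            cuts.add(ev.root_end + 1)
        cut_list = sorted(cuts)
        segments = [(a, b - 1) for a, b in zip(cut_list, cut_list[1:])]

        blocks: List[AlignedBlock] = []
        cursors = {iso: 1 for iso in self.names}
        k = 1
        for S, E in segments:
            gapped_rows = self._segment_rows(S, E)
            rows = []
            for iso in self.names:
                gapped, inverted = gapped_rows[iso]
                body = ungap(gapped)
                if not body:
                    continue
                start = cursors[iso]
                end = start + len(body) - 1
                cursors[iso] = end + 1
                rows.append(AlignedRow(iso, gapped, start, end, "-" if inverted else "+"))
            if rows:
                blocks.append(AlignedBlock(f"Aln_{k}", rows))
                k += 1
        for iso in self.names:
            if cursors[iso] != len(self.genomes[iso]) + 1:
                raise SyntheticError(
                    f"internal error: decomposition does not tile {iso!r}"
                )
        return BlockDecomposition(blocks, self.genome_lengths)

    def _segment_rows(self, S: int, E: int) -> Dict[str, Tuple[str, bool]]:
        """Gapped alignment rows of root segment [S, E], root as template.

        Each genome's insertions get private columns; a genome whose
        inversion covers the segment contributes the exact root slice on the
        '-' strand (inversions are exclusion zones for all other events).
        """
        chars: Dict[str, Dict[int, str]] = {}
        ins_after: Dict[str, Dict[int, str]] = {}
        inverted: Dict[str, bool] = {}
        for iso in self.names:
            truth = self.truths[iso]
            inverted[iso] = any(
                ev.root_start <= S and E <= ev.root_end for ev in truth.inversions()
            )
            cmap = {p: self.root[p - 1] for p in range(S, E + 1)}
            imap: Dict[int, str] = {}
            if not inverted[iso]:
                for ev in truth.events:
                    if ev.kind == "inversion" or ev.root_end < S or ev.root_start > E:
                        if not (ev.kind == "insertion" and ev.root_start == S - 1 == 0):
                            continue
                    if ev.kind == "substitution":
                        cmap[ev.root_start] = str(ev.payload)
                    elif ev.kind == "deletion":
                        for p in range(ev.root_start, ev.root_end + 1):
                            cmap[p] = ""
                    elif ev.kind == "insertion":
                        key = ev.root_start
                        imap[key] = imap.get(key, "") + str(ev.payload)
                    elif ev.kind == "tandem_expansion":
                        unit = self.root[ev.root_start - 1 : ev.root_end]
                        imap[ev.root_end] = imap.get(ev.root_end, "") + unit * int(ev.payload)
            chars[iso] = cmap
            ins_after[iso] = imap

        parts: Dict[str, List[str]] = {iso: [] for iso in self.names}

        def insertion_columns(anchor: int) -> None:
            for owner in self.names:
                payload = ins_after[owner].get(anchor, "")
                if payload:
                    for iso in self.names:
                        parts[iso].append(payload if iso == owner else "-" * len(payload))

        if S == 1:
            insertion_columns(0)
        for p in range(S, E + 1):
            for iso in self.names:
                if inverted[iso]:
                    parts[iso].append(self.root[p - 1])
                else:
                    parts[iso].append(chars[iso][p] or "-")
            insertion_columns(p)
        return {iso: ("".join(parts[iso]), inverted[iso]) for iso in self.names}

    # -- writers -------------------------------------------------------------

    def write_fasta(self, directory) -> Dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for iso in self.names:
            path = directory / f"{iso}.fasta"
            write_fasta(path, {iso: self.genomes[iso]})
            paths[iso] = path
        return paths

    def write_manifest(self, path, fasta_paths: Mapping[str, Path]) -> None:
        with open(path, "w") as handle:
            for iso in self.names:
                handle.write(f"{iso}\t{fasta_paths[iso]}\n")

    def write_xmfa(self, path) -> None:
        decomp = self.decomposition()
        index = {iso: i + 1 for i, iso in enumerate(self.names)}
        with open(path, "w") as handle:
            handle.write("#FormatVersion Mauve1\n")
            for block in decomp.blocks:
                for row in block.rows:
                    handle.write(
                        f"> {index[row.isolate]}:{row.start}-{row.end} {row.strand} {row.isolate}\n"
                    )
                    for i in range(0, len(row.gapped_seq), 80):
                        handle.write(row.gapped_seq[i : i + 80] + "\n")
                handle.write("=\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("isolate\tkind\troot_start\troot_end\tpayload\n")
            for iso in self.names:
                for ev in self.truths[iso].events:
                    payload = "" if ev.payload is None else str(ev.payload)
                    handle.write(
                        f"{iso}\t{ev.kind}\t{ev.root_start}\t{ev.root_end}\t{payload}\n"
                    )


def make_fixture_set(
    n_genomes: int,
    root_length: int = 10000,
    rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
) -> FixtureSet:
    """Generate a deterministic fixture set of related genomes.

    ``rates["inv_count"]`` is the total number of inversions across the set,
    each assigned to a randomly chosen mutated isolate; the other rates are
    per genome.  Inversion intervals (with a 1 bp guard) are excluded from
    every genome's other events so that the derived block decomposition has
    clean breakpoints.  The same seed yields byte-identical fixtures.
    """
    if n_genomes < 1:
        raise SyntheticError("n_genomes must be >= 1")
    rates = _resolve_rates(rates)
    rng = np.random.default_rng(seed)
    root = random_genome(root_length, rng)
    names = list(names) if names else [f"iso{i}" for i in range(1, n_genomes + 1)]
    if len(names) != n_genomes:
        raise SyntheticError("names must have one entry per genome")

    inv_total = int(rates["inv_count"]) if n_genomes > 1 else 0
    inv_lo = max(20, root_length // 20)
    inv_hi = max(inv_lo + 10, root_length // 8)
    planned: List[Tuple[str, MutationEvent]] = []
    occupied: List[Tuple[int, int]] = []
    for _ in range(inv_total):
        for _attempt in range(200):
            length = int(rng.integers(inv_lo, inv_hi + 1))
            if length + 4 > root_length:
                continue
            s = int(rng.integers(2, root_length - length))
            e = s + length - 1
            if all(e + 2 < a or s - 2 > b for a, b in occupied):
                target = names[1 + int(rng.integers(n_genomes - 1))]
                planned.append((target, MutationEvent("inversion", s, e)))
                occupied.append((s, e))
                break
        else:
            raise SyntheticError(
                f"could not place {inv_total} inversions on a {root_length} bp root"
            )
    forbidden = [(s - 1, e + 1) for s, e in occupied]

    child_seeds = rng.integers(0, 2**31 - 1, size=n_genomes)
    per_genome_rates = dict(rates)
    per_genome_rates["inv_count"] = 0
    genomes = {names[0]: root}
    truths = {names[0]: MutationTruth([], root_length, root_length,
                                      apply_events(root, [])[1])}
    for j in range(1, n_genomes):
        forced = [ev for iso, ev in planned if iso == names[j]]
        derived, truth = mutate_genome(
            root,
            per_genome_rates,
            seed=int(child_seeds[j]),
            forced_events=forced,
            forbidden=forbidden,
        )
        genomes[names[j]] = derived
        truths[names[j]] = truth
    return FixtureSet(names, root, genomes, truths)


def make_homology_fixture(
    seed: int = 0,
    n_genomes: int = 3,
    n_genes: int = 5,
    gene_length: int = 300,
    spacer: int = 200,
):
    """A fixture for positional orthology: ``n_genes`` genes on the root,
    the last being a high-identity paralogue of the second at a distinct
    locus, annotated per isolate with isolate-local gene ids.

    Returns ``(fixture, annotations, expected)`` where ``annotations`` maps
    isolate -> FeatureRecords (lifted via the truth coordinate map) and
    ``expected`` is the true ortholog table (rows: reference gene ids).
    """
    from .query import FeatureRecord  # local import to avoid a cycle
    import pandas as pd

    if n_genes < 2:
        raise SyntheticError("need at least two genes for the paralogue pair")
    rng = np.random.default_rng(seed)
    names = [f"iso{i}" for i in range(1, n_genomes + 1)]

    gene_seqs = [random_genome(gene_length, rng) for _ in range(n_genes)]
    # paralogue pair: last gene is the second gene with two substitutions
    paralogue = list(gene_seqs[1])
    for pos in rng.choice(gene_length, size=2, replace=False):
        paralogue[pos] = next(b for b in BASES if b != paralogue[pos])
    gene_seqs[-1] = "".join(paralogue)

    pieces = [random_genome(spacer, rng)]
    gene_intervals: List[Tuple[int, int]] = []
    cursor = spacer
    for seq in gene_seqs:
        gene_intervals.append((cursor + 1, cursor + gene_length))
        pieces.append(seq)
        cursor += gene_length
        pieces.append(random_genome(spacer, rng))
        cursor += spacer
    root = "".join(pieces)

    forbidden = []
    for start, end in gene_intervals:
        forbidden.append((start - 2, start + 2))
        forbidden.append((end - 2, end + 2))

    child_seeds = rng.integers(0, 2**31 - 1, size=n_genomes)
    genomes = {names[0]: root}
    truths = {names[0]: MutationTruth([], len(root), len(root),
                                      apply_events(root, [])[1])}
    mut_rates = {"sub_rate": 0.005, "ins_rate": 0.0005, "del_rate": 0.0005,
                 "inv_count": 0, "repeat_expansions": 0}
    for j in range(1, n_genomes):
        derived, truth = mutate_genome(
            root, mut_rates, seed=int(child_seeds[j]), forbidden=forbidden
        )
        genomes[names[j]] = derived
        truths[names[j]] = truth
    fixture = FixtureSet(names, root, genomes, truths)

    annotations: Dict[str, List[FeatureRecord]] = {}
    for iso in names:
        truth = truths[iso]
        features = []
        for k, (start, end) in enumerate(gene_intervals, 1):
            lifted_start = truth.root_to_derived(start)
            lifted_end = truth.root_to_derived(end)
            strand = "-" if k == min(3, n_genes) else "+"
            features.append(
                FeatureRecord(
                    isolate=iso,
                    seqid=iso,
                    feature_type="gene",
                    start=lifted_start,
                    end=lifted_end,
                    strand=strand,
                    attributes={"gene_id": f"{iso}_g{k}"},
                )
            )
        annotations[iso] = features

    ref = names[0]
    expected = pd.DataFrame(
        {iso: [f"{iso}_g{k}" for k in range(1, n_genes + 1)] for iso in names},
        index=pd.Index([f"{ref}_g{k}" for k in range(1, n_genes + 1)], name="gene"),
    )
    return fixture, annotations, expected
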