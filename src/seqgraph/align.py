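"""Block alignment: a built-in global aligner and external MSA tool wrappers.

The toolkit delegates hard alignment problems to established MSA tools
(mafft, muscle, clustalo); the built-in pairwise/progressive aligner exists
so that graphs can be built and tested without external binaries.  The
pairwise aligner is a Needleman-Wunsch/Gotoh dynamic program with affine
gaps: a gap of length ``L`` scores ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import GAP, check_nucleotides, read_fasta, ungap, write_fasta

#: Default scoring. Gap costs favour one long gap over several short ones,
#: matching the block-wise indel structure of closely related genomes.
DEFAULT_SCORING: Dict[str, float] = {
    "match": 1.0,
    "mismatch": -1.0,
    "gap_open": -2.0,
    "gap_extend": -0.5,
}

_NEG = -1e18


class AlignmentError(Exception):
    pass


class AlignerUnavailableError(AlignmentError):
    """The requested external aligner executable cannot be found."""


@dataclass
class AlignedRow:
    """One gapped row of a block alignment.

    ``start``/``end`` are 1-based inclusive forward-strand genomic
    coordinates of the ungapped segment; ``strand == "-"`` means
    ``gapped_seq`` is the reverse-complement of the forward-strand slice.
    """

    isolate: str
    gapped_seq: str
    start: int
    end: int
    strand: str = "+"

    def ungapped(self) -> str:
        return ungap(self.gapped_seq)


@dataclass
class AlignedBlock:
    """A gapped multiple alignment of one co-linear block."""

    block_id: str
    rows: List[AlignedRow] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0].gapped_seq) if self.rows else 0

    def row_for(self, isolate: str) -> AlignedRow:
        for row in self.rows:
            if row.isolate == isolate:
                return row
        raise KeyError(isolate)

    def isolates(self) -> List[str]:
        return [r.isolate for r in self.rows]

    def validate(self) -> None:
        if not self.rows:
            raise AlignmentError(f"block {self.block_id!r}: no rows")
        width = self.width
        if width < 1:
            raise AlignmentError(f"block {self.block_id!r}: zero-width alignment")
        for row in self.rows:
            if len(row.gapped_seq) != width:
                raise AlignmentError(
                    f"block {self.block_id!r}: row {row.isolate!r} has length "
                    f"{len(row.gapped_seq)}, expected {width}"
                )
            check_nucleotides(row.gapped_seq, allow_gaps=True,
                              context=f"block {self.block_id!r} row {row.isolate!r}")
            if row.strand not in "+-":
                raise AlignmentError(
                    f"block {self.block_id!r}: row {row.isolate!r} bad strand {row.strand!r}")
            if not (1 <= row.start <= row.end):
                raise AlignmentError(
                    f"block {self.block_id!r}: row {row.isolate!r} bad interval "
                    f"({row.start}, {row.end})"
                )
            if len(row.ungapped()) != row.end - row.start + 1:
                raise AlignmentError(
                    f"block {self.block_id!r}: row {row.isolate!r} ungapped length "
                    f"{len(row.ungapped())} != interval span {row.end - row.start + 1}"
                )
        for col in range(width):
            if all(r.gapped_seq[col] == GAP for r in self.rows):
                raise AlignmentError(
                    f"block {self.block_id!r}: column {col} is all gaps")


def _resolve_scoring(scoring: Optional[Mapping[str, float]]) -> Dict[str, float]:
    out = dict(DEFAULT_SCORING)
    if scoring:
        unknown = set(scoring) - set(DEFAULT_SCORING)
        if unknown:
            raise ValueError(f"unknown scoring keys {sorted(unknown)}")
        out.update(scoring)
    return out


def pairwise_global_align(
    a: str,
    b: str,
    scoring: Optional[Mapping[str, float]] = None,
) -> Tuple[str, str, float]:
    """Optimal global alignment of ``a`` and ``b`` with affine gap costs.

    Returns ``(gapped_a, gapped_b, score)``.  Tie-breaking in traceback
    prefers diagonal over up (gap in ``b``) over left (gap in ``a``), so the
    result is deterministic.
    """
    sc = _resolve_scoring(scoring)
    a, b = a.upper(), b.upper()
    check_nucleotides(a, context="first sequence")
    check_nucleotides(b, context="second sequence")
    m, n = len(a), len(b)
    go, ge = sc["gap_open"], sc["gap_extend"]
    if m == 0 or n == 0:
        if m == n == 0:
            return "", "", 0.0
        score = go + ge * max(m, n)
        return (a, GAP * m, score) if n == 0 else (GAP * n, b, score)

    match, mismatch = sc["match"], sc["mismatch"]
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)

    # Three-state Gotoh: M ends in a match/mismatch column, X in a gap in b
    # (a consumed; "up"), Y in a gap in a ("left"). X<->Y transitions are
    # allowed so adjacent insertions and deletions each pay their own open.
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)
    Y = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    X[1:, 0] = go + ge * np.arange(1, m + 1)
    Y[0, 1:] = go + ge * np.arange(1, n + 1)
    jix = np.arange(n + 1)
    for i in range(1, m + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) + go + ge, X[i - 1] + ge)
        # Y within the row via a running max: Y[i,j] = ge*j + max_{k<j} W[k]
        W = np.maximum(M[i], X[i]) + go - ge * jix
        run = np.maximum.accumulate(W)
        Y[i, 1:] = ge * jix[1:] + run[:-1]
        Y[i, 0] = _NEG

    eps = 1e-6
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = m, n
    finals = {"M": M[m, n], "X": X[m, n], "Y": Y[m, n]}
    state = max(("M", "X", "Y"), key=lambda s: (finals[s], s == "M", s == "X"))
    score = finals[state]
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - (match if a[i - 1] == b[j - 1] else mismatch)
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < eps:
                    state = s
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + go + ge - val) < eps:
                state = "M"
            elif abs(X[i, j] + ge - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + go + ge - val) < eps:
                state = "M"
            elif abs(X[i, j] + go + ge - val) < eps:
                state = "X"
            else:
                state = "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def _consensus(rows: Sequence[str]) -> str:
    """Majority non-gap character per column; ties broken lexicographically."""
    out = []
    for col in zip(*rows):
        counts: Dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def progressive_msa(
    seqs: Mapping[str, str],
    scoring: Optional[Mapping[str, float]] = None,
    block_id: str = "Aln_1",
) -> AlignedBlock:
    """Progressive multiple alignment in input order.

    Each sequence is aligned against the majority-character consensus of the
    running profile; gaps opened in the consensus are propagated to all
    previous rows.  Adequate for the highly similar within-block sequences
    this toolkit collapses; external tools are the intended path for harder
    inputs.
    """
    if not seqs:
        raise AlignmentError("progressive_msa requires at least one sequence")
    isolates = list(seqs)
    rows: List[str] = [seqs[isolates[0]].upper()]
    check_nucleotides(rows[0], context=f"sequence {isolates[0]!r}")
    for isolate in isolates[1:]:
        seq = seqs[isolate].upper()
        cons = _consensus(rows)
        g_cons, g_new, _ = pairwise_global_align(cons, seq, scoring)
        # re-expand profile rows through the gaps inserted into the consensus
        new_rows = []
        for row in rows:
            rebuilt = []
            pos = 0
            for c in g_cons:
                if c == GAP:
                    rebuilt.append(GAP)
                else:
                    rebuilt.append(row[pos])
                    pos += 1
            new_rows.append("".join(rebuilt))
        new_rows.append(g_new)
        rows = new_rows
    block = AlignedBlock(
        block_id,
        [
            AlignedRow(isolate, row, 1, len(ungap(row)), "+")
            for isolate, row in zip(isolates, rows)
        ],
    )
    block.validate()
    return block


_TOOL_EXES = {"mafft": "mafft", "muscle": "muscle", "clustalo": "clustalo"}


def run_external_aligner(
    tool: str,
    seqs: Mapping[str, str],
    options: Sequence[str] = (),
) -> AlignedBlock:
    """Align ``seqs`` with an external MSA tool (mafft, muscle or clustalo).

    Raises :class:`AlignerUnavailableError` when the executable is missing,
    and :class:`AlignmentError` (with captured diagnostics) on tool failure
    or unparseable output.  Output rows are reordered to input order and
    checked to ungap back to their inputs.
    """
    if tool not in _TOOL_EXES:
        raise ValueError(f"unknown aligner {tool!r}; expected one of {sorted(_TOOL_EXES)}")
    exe = shutil.which(_TOOL_EXES[tool])
    if exe is None:
        raise AlignerUnavailableError(f"aligner unavailable: {tool!r} not on PATH")
    if not seqs:
        raise AlignmentError("run_external_aligner requires at least one sequence")
    with tempfile.TemporaryDirectory(prefix="seqgraph_msa_") as tmp:
        infile = Path(tmp) / "input.fasta"
        outfile = Path(tmp) / "output.fasta"
        write_fasta(infile, {k: v.upper() for k, v in seqs.items()})
        if tool == "mafft":
            cmd = [exe, *(options or ("--auto", "--quiet")), str(infile)]
            capture_to = outfile
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode == 0:
                capture_to.write_text(proc.stdout)
        elif tool == "clustalo":
            cmd = [exe, "-i", str(infile), "-o", str(outfile), "--force", *options]
            proc = subprocess.run(cmd, capture_output=True, text=True)
        else:  # muscle; v5 and v3 differ in flags
            cmd = [exe, "-align", str(infile), "-output", str(outfile), *options]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                cmd = [exe, "-in", str(infile), "-out", str(outfile), *options]
                proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignmentError(
                f"{tool} exited with status {proc.returncode}: {proc.stderr.strip()}"
            )
        try:
            aligned = read_fasta(outfile)
        except Exception as exc:  # pragma: no cover - tool-specific breakage
            raise AlignmentError(f"could not parse {tool} output: {exc}") from exc
    if set(aligned) != set(seqs):
        raise AlignmentError(
            f"{tool} output records {sorted(aligned)} do not match input {sorted(seqs)}"
        )
    rows = []
    for isolate in seqs:
        g = aligned[isolate]
        if ungap(g) != seqs[isolate].upper():
            raise AlignmentError(
                f"{tool} output for {isolate!r} does not ungap to its input"
            )
        rows.append(AlignedRow(isolate, g, 1, len(ungap(g)), "+"))
    block = AlignedBlock("Aln_1", rows)
    block.validate()
    return block
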