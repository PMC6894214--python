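"""Small sequence helpers shared across modules."""

from __future__ import annotations

from typing import Dict, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

#: Nucleotide characters accepted in node sequences (IUPAC, no gaps).
NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")
GAP = "-"


def revcomp(seq: str) -> str:
    """Reverse-complement ``seq`` (IUPAC-aware; gaps are preserved)."""
    return str(Seq(seq).reverse_complement())


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def check_nucleotides(seq: str, *, allow_gaps: bool = False, context: str = "") -> None:
    allowed = NUCLEOTIDES | {GAP} if allow_gaps else NUCLEOTIDES
    bad = set(seq.upper()) - allowed
    if bad:
        where = f" in {context}" if context else ""
        raise ValueError(f"non-nucleotide characters {sorted(bad)}{where}")


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{record id: uppercase sequence}`` map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Mapping[str, str], wrap: int = 70) -> None:
    """Write ``{name: sequence}`` to a path or open handle, wrapped at
    ``wrap`` columns."""
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items())
    if hasattr(path, "write"):
        FastaWriter(path, wrap=wrap).write_file(recs)
    else:
        with open(path, "w") as handle:
            FastaWriter(handle, wrap=wrap).write_file(recs)
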