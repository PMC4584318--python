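"""Small shared sequence helpers (DNA alphabet, complements, FASTA I/O)."""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, entries: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in entries]
    SeqIO.write(records, str(path), "fasta")
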