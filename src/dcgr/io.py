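"""FASTA input/output for protein sequence records."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

from Bio import SeqIO


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id (first header token), description remainder,
    uppercased residue string."""

    id: str
    description: str
    residues: str


def read_fasta(stream: TextIO) -> list[SequenceRecord]:
    """Parse multi-line FASTA; blank lines ignored, sequences uppercased.

    Raises
    ------
    ValueError
        On an empty sequence, a duplicate id, or input with no records.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=seq))
    if not records:
        raise ValueError("no FASTA records found in input")
    return records


def write_fasta(records: list[SequenceRecord], stream: TextIO, width: int = 60) -> None:
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        stream.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            stream.write(rec.residues[i:i + width] + "\n")
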