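"""FASTA input as plain sequence records.

Parsing is delegated to Biopython's ``Bio.SeqIO``; a light pre-scan supplies
the line-numbered errors a shell user needs when a file is not FASTA at all.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .errors import FastaFormatError

__all__ = ["SequenceRecord", "read_fasta"]


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a raw symbol string."""

    id: str
    description: str
    seq: str


def _check_leading_garbage(lines: Iterable[str]) -> None:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaFormatError(
                "sequence data before the first '>' header", line=lineno
            )
        return
    raise FastaFormatError("no FASTA records found")


def read_fasta(source: str | Path | IO[str], *, upper: bool = False) -> list[SequenceRecord]:
    """Read all records of a FASTA file or text stream.

    Wrapped sequence lines are concatenated and record order preserved.
    *upper* upper-cases the sequences (convenient when mixing genome FASTA
    with lowercase literals).  Raises :class:`FastaFormatError` on input with
    data before the first header or with no records.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    _check_leading_garbage(text.splitlines())
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if upper:
            seq = seq.upper()
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, description, seq))
    if not records:
        raise FastaFormatError("no FASTA records found")
    return records
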