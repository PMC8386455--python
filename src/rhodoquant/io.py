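"""Protein records and FASTA input/output.

FASTA parsing is delegated to :mod:`Bio.SeqIO`; identifiers follow the
``>`` first-token convention. Sequences are uppercased and validated
against the engine alphabet on ingest (stop characters ``*`` stripped
with a warning).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import clean_sequence
from .errors import InvalidInputError


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with identifier and optional labels.

    ``taxon`` and ``source_sample`` are carried through screening and
    annotation untouched; they exist so synthetic ground truth and real
    sample provenance can ride along with the sequence.
    """

    id: str
    sequence: str
    taxon: str | None = None
    source_sample: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("protein record needs a nonempty id")
        object.__setattr__(
            self, "sequence", clean_sequence(self.sequence, f"record {self.id}")
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "ProteinRecord":
        return replace(self, sequence=sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file (wrapped or single-line)."""
    path = Path(path)
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as single-line FASTA (id only on the header)."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta-2line")
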