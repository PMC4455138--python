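"""Reference transcriptome container and FASTA I/O.

A reference is an ordered mapping of gene id to nucleotide sequence, one
record per gene. It is the substrate for tag-index construction and for
drawing simulated tag reads.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.errors import FormatError


@dataclass
class ReferenceTranscriptome(Mapping):
    """Ordered gene id -> sequence mapping with FASTA round-tripping."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = {str(k): str(v).upper() for k, v in self.records.items()}

    def __getitem__(self, gene_id: str) -> str:
        return self.records[gene_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceTranscriptome":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate gene id in FASTA: {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = (
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in self.records.items()
        )
        SeqIO.write(recs, str(path), "fasta")
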