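"""Raw tag read container and FASTQ I/O.

Reads are stored as fixed-width numpy byte-string arrays, which keeps a
multi-million-read library compact and lets the cleaning stage vectorize.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from tagdge.errors import FormatError


@dataclass
class RawReads:
    """A raw sequencing library: parallel sequence and quality arrays."""

    sequences: np.ndarray
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=bytes)
        self.qualities = np.asarray(self.qualities, dtype=bytes)
        if self.sequences.shape != self.qualities.shape:
            raise FormatError("sequence and quality arrays differ in length")

    def __len__(self) -> int:
        return int(self.sequences.shape[0])

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for seq, qual in zip(self.sequences, self.qualities):
            yield seq.decode(), qual.decode()

    @classmethod
    def from_pairs(cls, pairs) -> "RawReads":
        pairs = list(pairs)
        seqs = np.array([p[0] for p in pairs], dtype=bytes)
        quals = np.array([p[1] for p in pairs], dtype=bytes)
        return cls(seqs, quals)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "RawReads":
        seqs: list[str] = []
        quals: list[str] = []
        with open(path) as handle:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    if len(seq) != len(qual):
                        raise FormatError(
                            f"FASTQ record {title.split()[0]!r}: sequence and "
                            f"quality lengths differ"
                        )
                    seqs.append(seq.upper())
                    quals.append(qual)
            except ValueError as exc:  # biopython's malformed-record error
                raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc
        if not seqs:
            return cls(np.empty(0, dtype="S1"), np.empty(0, dtype="S1"))
        return cls(np.array(seqs, dtype=bytes), np.array(quals, dtype=bytes))

    def to_fastq(self, path: str | Path, id_prefix: str = "read") -> None:
        with open(path, "w") as handle:
            for i, (seq, qual) in enumerate(self):
                handle.write(f"@{id_prefix}_{i}\n{seq}\n+\n{qual}\n")
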