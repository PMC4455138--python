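"""Raw-read cleaning and distinct-tag counting.

Cleaning removes adaptor-containing reads and low-quality reads (any base
below a Phred threshold, or any ambiguous base), truncates longer reads
to the 21-nt tag length, and aggregates survivors into a distinct-tag
count table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tagdge.errors import FormatError, InputError
from tagdge.reads import RawReads

TAG_LENGTH = 21
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"  # 21 nt, configurable everywhere
DEFAULT_QUALITY_THRESHOLD = 10  # Phred; any base below this drops the read
_PHRED_OFFSET = 33
_TAG_BYTES = frozenset(b"ACGT")


@dataclass
class TagLibrary:
    """One library's distinct clean tags with copy counts and totals."""

    library_id: str
    raw_total: int
    clean_total: int
    tag_counts: dict[str, int] = field(default_factory=dict)
    raw_distinct: int | None = None

    def __post_init__(self) -> None:
        if self.clean_total != sum(self.tag_counts.values()):
            raise InputError(
                f"clean_total {self.clean_total} != sum of tag counts "
                f"{sum(self.tag_counts.values())}"
            )
        if self.clean_total > self.raw_total:
            raise InputError("clean_total exceeds raw_total")
        for tag, count in self.tag_counts.items():
            if len(tag) != TAG_LENGTH or not set(tag) <= set("ACGT"):
                raise InputError(f"invalid tag {tag!r}")
            if count <= 0:
                raise InputError(f"non-positive count for tag {tag!r}")

    @property
    def distinct_tags(self) -> int:
        return len(self.tag_counts)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            sorted(self.tag_counts.items()), columns=["tag", "count"]
        )
        frame.to_csv(path, sep="\t", index=False)

    def summary_to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(library_summary(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        library_id: str | None = None,
        raw_total: int | None = None,
        raw_distinct: int | None = None,
    ) -> "TagLibrary":
        """Load a pre-counted two-column (tag, count) table."""
        frame = pd.read_csv(path, sep="\t", dtype={"tag": str})
        for column in ("tag", "count"):
            if column not in frame.columns:
                raise FormatError(f"tag table {path} is missing column {column!r}")
        counts = {
            str(tag): int(count)
            for tag, count in zip(frame["tag"], frame["count"])
        }
        clean_total = sum(counts.values())
        return cls(
            library_id=library_id or Path(path).stem,
            raw_total=clean_total if raw_total is None else raw_total,
            clean_total=clean_total,
            tag_counts=counts,
            raw_distinct=raw_distinct,
        )


def _clean_fixed_width(
    reads: RawReads, adaptor: bytes, min_qual_char: int
) -> tuple[Counter, int]:
    """Vectorized cleaning for the common all-21-nt case."""
    n = len(reads)
    seqs = reads.sequences
    quals = reads.qualities
    keep = np.ones(n, dtype=bool)
    # adaptor containment (equality when read and adaptor lengths match)
    keep &= np.char.find(seqs, adaptor) < 0
    qmat = quals.view(np.uint8).reshape(n, TAG_LENGTH)
    keep &= (qmat >= min_qual_char).all(axis=1)
    smat = seqs.view(np.uint8).reshape(n, TAG_LENGTH)
    valid = np.zeros(256, dtype=bool)
    valid[list(_TAG_BYTES)] = True
    keep &= valid[smat].all(axis=1)
    survivors = seqs[keep]
    tags, counts = np.unique(survivors, return_counts=True)
    counter = Counter(
        {tag.decode(): int(count) for tag, count in zip(tags, counts)}
    )
    return counter, int(keep.sum())


def _clean_generic(reads, adaptor: str, threshold: int) -> tuple[Counter, int, int]:
    """Per-read cleaning for arbitrary iterables of (seq, qual) pairs."""
    counter: Counter = Counter()
    raw_total = 0
    clean_total = 0
    min_qual_char = _PHRED_OFFSET + threshold
    for record in reads:
        raw_total += 1
        seq, qual = record
        seq = seq.upper()
        if len(seq) != len(qual):
            raise FormatError(
                f"read #{raw_total}: sequence and quality lengths differ"
            )
        if adaptor and adaptor in seq:
            continue
        if len(seq) > TAG_LENGTH:  # truncate to tag length after adaptor check
            seq = seq[:TAG_LENGTH]
            qual = qual[:TAG_LENGTH]
        if len(seq) < TAG_LENGTH:
            continue
        if not set(seq) <= set("ACGT"):
            continue
        if any(ord(q) < min_qual_char for q in qual):
            continue
        counter[seq] += 1
        clean_total += 1
    return counter, raw_total, clean_total


def extract_clean_tags(
    reads,
    adaptor: str = DEFAULT_ADAPTOR,
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    library_id: str = "library",
    min_copies: int = 1,
) -> TagLibrary:
    """Build a :class:`TagLibrary` from raw reads.

    ``reads`` is a :class:`RawReads` library or any iterable of
    ``(sequence, quality)`` string pairs. Reads containing the adaptor,
    reads with any base below ``quality_threshold`` (Phred+33) and reads
    with ambiguous bases are removed; longer reads are truncated to 21 nt.
    ``min_copies`` optionally drops rare tags after aggregation (default
    keeps everything, including singletons).
    """
    raw_distinct = None
    adaptor = adaptor.upper() if adaptor else ""
    if isinstance(reads, RawReads):
        raw_total = len(reads)
        raw_distinct = int(np.unique(reads.sequences).size) if raw_total else 0
        if raw_total and reads.sequences.dtype.itemsize == TAG_LENGTH == reads.qualities.dtype.itemsize:
            counter, clean_total = _clean_fixed_width(
                reads, adaptor.encode(), _PHRED_OFFSET + quality_threshold
            )
        else:
            counter, _, clean_total = _clean_generic(
                iter(reads), adaptor, quality_threshold
            )
    else:
        counter, raw_total, clean_total = _clean_generic(
            reads, adaptor, quality_threshold
        )
    if min_copies > 1:
        dropped = {tag: c for tag, c in counter.items() if c < min_copies}
        for tag, count in dropped.items():
            del counter[tag]
            clean_total -= count
    return TagLibrary(
        library_id=library_id,
        raw_total=raw_total,
        clean_total=clean_total,
        tag_counts=dict(sorted(counter.items())),
        raw_distinct=raw_distinct,
    )


def library_summary(lib: TagLibrary) -> dict[str, int]:
    """Raw/clean totals and the distinct clean tag count."""
    summary = {
        "library_id": lib.library_id,
        "raw_total": lib.raw_total,
        "clean_total": lib.clean_total,
        "distinct_tags": lib.distinct_tags,
    }
    if lib.raw_distinct is not None:
        summary["raw_distinct"] = lib.raw_distinct
    return summary
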