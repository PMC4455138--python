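"""Exact-match tag indexing and mapping.

Every ``CATG`` anchored 21-nt window of each reference gene (and, by
default, of its reverse complement) is indexed. Clean tags are then
classified against the index with no mismatches allowed: a tag hitting
exactly one gene is *unambiguous* and contributes its copies to that
gene's count; a tag hitting several genes is *ambiguous* and is excluded
from gene counts; everything else is *unmapped*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from tagdge._util import percent, reverse_complement
from tagdge.errors import InputError, UndefinedStatisticError
from tagdge.reference import ReferenceTranscriptome
from tagdge.tags import TagLibrary

logger = logging.getLogger(__name__)

ANCHOR = "CATG"
TAG_LENGTH = 21  # CATG + 17 nt of downstream transcript sequence
_VALID = frozenset("ACGT")


@dataclass
class TagIndex:
    """Map from 21-nt tag to the set of ``(gene_id, strand, offset)`` hits.

    Offsets are 0-based window starts on the scanned strand, windows are
    half-open ``[start, start + 21)``.
    """

    reference_size: int
    entries: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)
    both_strands: bool = True

    def __post_init__(self) -> None:
        for tag, hits in self.entries.items():
            if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
                raise InputError(f"invalid index tag {tag!r}")
            if not hits:
                raise InputError(f"index tag {tag!r} has an empty hit set")

    def genes_for(self, tag: str) -> set[str]:
        return {gene for gene, _, _ in self.entries.get(tag, ())}

    def to_tsv(self, path) -> None:
        rows = [
            (tag, gene, strand, offset)
            for tag in sorted(self.entries)
            for gene, strand, offset in sorted(self.entries[tag])
        ]
        frame = pd.DataFrame(rows, columns=["tag", "gene_id", "strand", "offset"])
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference_size: int, both_strands: bool = True) -> "TagIndex":
        frame = pd.read_csv(path, sep="\t", dtype={"tag": str, "gene_id": str})
        entries: dict[str, set[tuple[str, str, int]]] = {}
        for row in frame.itertuples(index=False):
            entries.setdefault(row.tag, set()).add(
                (row.gene_id, row.strand, int(row.offset))
            )
        return cls(reference_size, entries, both_strands)


@dataclass
class MappingResult:
    """Classification of one library's distinct clean tags against an index."""

    library_id: str
    gene_counts: dict[str, int] = field(default_factory=dict)
    distinct_mapped: int = 0  # unambiguous distinct tags
    distinct_ambiguous: int = 0
    distinct_unmapped: int = 0
    genes_all: int = 0  # genes hit by any mapped tag (ambiguous included)
    genes_unambiguous: int = 0  # genes hit by >=1 unambiguous tag

    @property
    def mapped_copies(self) -> int:
        return sum(self.gene_counts.values())

    def counts_to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            sorted(self.gene_counts.items()), columns=["gene_id", "count"]
        )
        frame.to_csv(path, sep="\t", index=False)


def _anchor_windows(seq: str):
    """Yield (offset, window) for every CATG+17 window in ``seq``."""
    start = seq.find(ANCHOR)
    while start != -1:
        if start + TAG_LENGTH <= len(seq):
            yield start, seq[start : start + TAG_LENGTH]
        start = seq.find(ANCHOR, start + 1)


def canonical_tag(seq: str) -> str | None:
    """The 3'-most CATG+17 window on the sense strand, or None.

    This is the tag that NlaIII DGE chemistry produces for a transcript,
    and the one the simulator emits for each sampled transcript copy.
    """
    seq = seq.upper()
    best = None
    for offset, window in _anchor_windows(seq):
        if set(window) <= _VALID:
            best = window
    return best


def build_tag_index(
    transcriptome: ReferenceTranscriptome, both_strands: bool = True
) -> TagIndex:
    """Index every anchored window of every gene (both strands by default).

    Windows containing non-ACGT characters are skipped with a warning.
    """
    if len(transcriptome) == 0:
        raise InputError("cannot index an empty transcriptome")
    entries: dict[str, set[tuple[str, str, int]]] = {}
    for gene_id, seq in transcriptome.items():
        seq = seq.upper()
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        for strand, strand_seq in strands:
            for offset, window in _anchor_windows(strand_seq):
                if not set(window) <= _VALID:
                    logger.warning(
                        "skipping window with non-ACGT base: gene %s strand %s "
                        "offset %d",
                        gene_id,
                        strand,
                        offset,
                    )
                    continue
                entries.setdefault(window, set()).add((gene_id, strand, offset))
    return TagIndex(len(transcriptome), entries, both_strands)


def map_tags(lib: TagLibrary, index: TagIndex) -> MappingResult:
    """Classify each distinct clean tag and accumulate unambiguous counts."""
    gene_counts: dict[str, int] = {}
    distinct_mapped = distinct_ambiguous = distinct_unmapped = 0
    genes_all: set[str] = set()
    genes_unambiguous: set[str] = set()
    for tag, copies in lib.tag_counts.items():
        hits = index.entries.get(tag)
        if hits is None:
            distinct_unmapped += 1
            continue
        genes = {gene for gene, _, _ in hits}
        genes_all.update(genes)
        if len(genes) == 1:
            distinct_mapped += 1
            (gene,) = genes
            gene_counts[gene] = gene_counts.get(gene, 0) + copies
            genes_unambiguous.add(gene)
        else:
            distinct_ambiguous += 1
    return MappingResult(
        library_id=lib.library_id,
        gene_counts=gene_counts,
        distinct_mapped=distinct_mapped,
        distinct_ambiguous=distinct_ambiguous,
        distinct_unmapped=distinct_unmapped,
        genes_all=len(genes_all),
        genes_unambiguous=len(genes_unambiguous),
    )


def tag_mapping_percentages(
    mapped_distinct: int,
    clean_distinct: int,
    genes_all: int,
    genes_unambiguous: int,
    reference_size: int,
) -> dict[str, float]:
    """Percentages as printed in library-statistics tables (half-up, 2 dp).

    ``mapped_distinct`` counts all gene-mapping distinct tags, ambiguous
    included, matching the "All tags mapping to gene" table row.
    """
    if reference_size == 0:
        raise UndefinedStatisticError("reference_size is zero")
    pct_mapped = (
        0.0 if clean_distinct == 0 else percent(mapped_distinct, clean_distinct, 2)
    )
    return {
        "pct_distinct_mapped_of_clean": pct_mapped,
        "pct_genes_all_of_reference": percent(genes_all, reference_size, 2),
        "pct_genes_unambiguous_of_reference": percent(
            genes_unambiguous, reference_size, 2
        ),
    }


def mapping_statistics(
    result: MappingResult, lib: TagLibrary | int, index: TagIndex | int
) -> dict[str, float]:
    """Table-style mapping percentages for one library.

    ``lib`` may be a :class:`TagLibrary` or a plain distinct-clean-tag
    count; ``index`` may be a :class:`TagIndex` or a plain reference size.
    """
    clean_distinct = lib.distinct_tags if isinstance(lib, TagLibrary) else int(lib)
    reference_size = (
        index.reference_size if isinstance(index, TagIndex) else int(index)
    )
    return tag_mapping_percentages(
        mapped_distinct=result.distinct_mapped + result.distinct_ambiguous,
        clean_distinct=clean_distinct,
        genes_all=result.genes_all,
        genes_unambiguous=result.genes_unambiguous,
        reference_size=reference_size,
    )
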