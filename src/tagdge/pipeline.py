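"""End-to-end orchestration for the two-species x two-host design.

A run cleans each library, maps it against its species reference,
normalizes to TPM, performs within-species differential comparisons, and
writes library-statistics, DEG, summary, and enrichment reports plus a
manifest, all deterministically (no timestamps), so reruns are
byte-identical. A verify step recomputes every report number from the
serialized intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tagdge import __version__ as _version
from tagdge._util import percent, round_half_up
from tagdge.diffexpr import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_LFC_THRESHOLD,
    call_degs,
    compute_tpm,
    pearson_correlation,
    summarize_degs,
)
from tagdge.enrichment import DEFAULT_P_THRESHOLD, load_annotation, enrich
from tagdge.errors import ConfigurationError, InputError
from tagdge.mapping import TagIndex, build_tag_index, map_tags
from tagdge.reads import RawReads
from tagdge.reference import ReferenceTranscriptome
from tagdge.tags import (
    DEFAULT_ADAPTOR,
    DEFAULT_QUALITY_THRESHOLD,
    TagLibrary,
    extract_clean_tags,
    library_summary,
)

logger = logging.getLogger(__name__)

TABLE1_ROWS = [
    ("Raw tag", "Total no. of tags", "raw_total"),
    ("Raw tag", "No. of distinct tags", "raw_distinct"),
    ("Clean tag", "Total number", "clean_total"),
    ("Clean tag", "Distinct Tag number", "clean_distinct"),
    ("All tags mapping to gene", "No. of distinct tags", "mapped_distinct"),
    ("All tags mapping to gene", "Distinct Tag % of clean tag", "pct_mapped"),
    ("All tag-mapped genes", "No. of genes", "genes_all"),
    ("All tag-mapped genes", "% of reference genes", "pct_genes_all"),
    ("Unambiguous tag-mapped genes", "No. of genes", "genes_unambiguous"),
    ("Unambiguous tag-mapped genes", "% of reference genes", "pct_genes_unambiguous"),
]


@dataclass
class Table1Stats:
    """Per-library sequencing/mapping statistics behind the report table."""

    raw_total: int = 0
    raw_distinct: int = 0
    clean_total: int = 0
    clean_distinct: int = 0
    mapped_distinct: int = 0  # all gene-mapping distinct tags, ambiguous included
    genes_all: int = 0
    genes_unambiguous: int = 0
    reference_size: int = 0

    def cells(self) -> dict[str, str]:
        def pct(num: int) -> str:
            if self.reference_size == 0:
                return "NA"
            return f"{percent(num, self.reference_size, 2):.2f}%"

        pct_mapped = (
            "0.00%"
            if self.clean_distinct == 0
            else f"{percent(self.mapped_distinct, self.clean_distinct, 2):.2f}%"
        )
        return {
            "raw_total": str(self.raw_total),
            "raw_distinct": str(self.raw_distinct),
            "clean_total": str(self.clean_total),
            "clean_distinct": str(self.clean_distinct),
            "mapped_distinct": str(self.mapped_distinct),
            "pct_mapped": pct_mapped,
            "genes_all": str(self.genes_all),
            "pct_genes_all": pct(self.genes_all),
            "genes_unambiguous": str(self.genes_unambiguous),
            "pct_genes_unambiguous": pct(self.genes_unambiguous),
        }


def collect_table1_stats(lib: TagLibrary, result, index: TagIndex) -> Table1Stats:
    return Table1Stats(
        raw_total=lib.raw_total,
        raw_distinct=lib.raw_distinct or 0,
        clean_total=lib.clean_total,
        clean_distinct=lib.distinct_tags,
        mapped_distinct=result.distinct_mapped + result.distinct_ambiguous,
        genes_all=result.genes_all,
        genes_unambiguous=result.genes_unambiguous,
        reference_size=index.reference_size,
    )


def table1_report(stats: dict[str, Table1Stats]) -> pd.DataFrame:
    """Library-statistics table with the canonical row labels.

    Columns are Category, Parameter, then one column per library id.
    With no libraries, an empty frame with the header columns is
    returned.
    """
    columns = ["Category", "Parameter", *stats]
    if not stats:
        return pd.DataFrame(columns=columns)
    cells = {lib_id: s.cells() for lib_id, s in stats.items()}
    rows = [
        [category, parameter, *(cells[lib_id][key] for lib_id in stats)]
        for category, parameter, key in TABLE1_ROWS
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class ComparisonSpec:
    """A within-species treated-vs-control comparison."""

    name: str
    treated: str
    control: str


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    references: dict[str, str]  # reference id -> FASTA path
    libraries: dict[str, dict]  # library id -> {reads|tags: path, reference: id}
    comparisons: list[ComparisonSpec] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)  # reference id -> TSV
    output_dir: str = "tagdge_run"
    adaptor: str = DEFAULT_ADAPTOR
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    enrich_p_threshold: float = DEFAULT_P_THRESHOLD
    both_strands: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        comparisons = [
            ComparisonSpec(
                name=c["name"], treated=c["treated"], control=c["control"]
            )
            for c in raw.get("comparisons", [])
        ]
        return cls(
            references=dict(raw["references"]),
            libraries={k: dict(v) for k, v in raw["libraries"].items()},
            comparisons=comparisons,
            annotations=dict(raw.get("annotations", {})),
            output_dir=raw.get("output_dir", "tagdge_run"),
            adaptor=raw.get("adaptor", DEFAULT_ADAPTOR),
            quality_threshold=int(
                raw.get("quality_threshold", DEFAULT_QUALITY_THRESHOLD)
            ),
            fdr_threshold=float(raw.get("fdr_threshold", DEFAULT_FDR_THRESHOLD)),
            lfc_threshold=float(raw.get("lfc_threshold", DEFAULT_LFC_THRESHOLD)),
            enrich_p_threshold=float(
                raw.get("enrich_p_threshold", DEFAULT_P_THRESHOLD)
            ),
            both_strands=bool(raw.get("both_strands", True)),
        )

    def validate(self) -> None:
        for lib_id, spec in self.libraries.items():
            ref = spec.get("reference")
            if ref not in self.references:
                raise ConfigurationError(
                    f"library {lib_id!r} names unknown reference {ref!r}"
                )
            if "reads" not in spec and "tags" not in spec:
                raise ConfigurationError(
                    f"library {lib_id!r} needs a 'reads' or 'tags' input"
                )
        for comparison in self.comparisons:
            for lib_id in (comparison.treated, comparison.control):
                if lib_id not in self.libraries:
                    raise ConfigurationError(
                        f"comparison {comparison.name!r} names unknown "
                        f"library {lib_id!r}"
                    )
            ref_t = self.libraries[comparison.treated]["reference"]
            ref_c = self.libraries[comparison.control]["reference"]
            if ref_t != ref_c:
                raise ConfigurationError(
                    f"comparison {comparison.name!r} crosses references "
                    f"{ref_t!r} vs {ref_c!r}; comparisons must stay within "
                    f"one species reference"
                )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the in-memory report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_hashes = {}
    for path in [
        *config.references.values(),
        *config.annotations.values(),
        *(
            spec.get("reads", spec.get("tags"))
            for spec in config.libraries.values()
        ),
    ]:
        p = Path(path)
        if not p.exists():
            raise InputError(f"missing input file: {p}")
        input_hashes[str(p)] = _sha256(p)

    references = {
        ref_id: ReferenceTranscriptome.from_fasta(path)
        for ref_id, path in config.references.items()
    }
    indexes = {
        ref_id: build_tag_index(ref, both_strands=config.both_strands)
        for ref_id, ref in references.items()
    }

    libraries: dict[str, TagLibrary] = {}
    results = {}
    stats: dict[str, Table1Stats] = {}
    for lib_id, spec in config.libraries.items():
        if "reads" in spec:
            reads = RawReads.from_fastq(spec["reads"])
            lib = extract_clean_tags(
                reads,
                adaptor=config.adaptor,
                quality_threshold=config.quality_threshold,
                library_id=lib_id,
            )
        else:
            lib = TagLibrary.from_tsv(spec["tags"], library_id=lib_id)
        logger.info(
            "library %s: %d raw -> %d clean (%d distinct)",
            lib_id, lib.raw_total, lib.clean_total, lib.distinct_tags,
        )
        index = indexes[spec["reference"]]
        result = map_tags(lib, index)
        logger.info(
            "library %s: distinct mapped/ambiguous/unmapped = %d/%d/%d",
            lib_id, result.distinct_mapped, result.distinct_ambiguous,
            result.distinct_unmapped,
        )
        libraries[lib_id] = lib
        results[lib_id] = result
        stats[lib_id] = collect_table1_stats(lib, result, index)
        lib.to_tsv(out / f"{lib_id}.tags.tsv")
        lib.summary_to_json(out / f"{lib_id}.summary.json")
        result.counts_to_tsv(out / f"{lib_id}.gene_counts.tsv")

    table1 = table1_report(stats)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    comparisons_report = {}
    for comparison in config.comparisons:
        ref_id = config.libraries[comparison.treated]["reference"]
        universe = references[ref_id].gene_ids
        profile_control = compute_tpm(
            results[comparison.control],
            libraries[comparison.control].clean_total,
            gene_universe=universe,
        )
        profile_treated = compute_tpm(
            results[comparison.treated],
            libraries[comparison.treated].clean_total,
            gene_universe=universe,
        )
        degs = call_degs(
            profile_control,
            profile_treated,
            fdr_threshold=config.fdr_threshold,
            lfc_threshold=config.lfc_threshold,
        )
        degs.to_csv(
            out / f"{comparison.name}.degs.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        summary = summarize_degs(degs)
        summary["pearson_r_log2_tpm"] = round_half_up(
            pearson_correlation(profile_control, profile_treated), 3
        )
        _write_json(summary, out / f"{comparison.name}.summary.json")

        enrichment_tables = {}
        if ref_id in config.annotations:
            annotation = load_annotation(config.annotations[ref_id])
            deg_genes = set(degs.loc[degs["status"] != "ns", "gene_id"])
            for category in annotation.categories:
                table = enrich(
                    deg_genes,
                    annotation,
                    category,
                    p_threshold=config.enrich_p_threshold,
                )
                table.to_csv(
                    out / f"{comparison.name}.enrichment.{category}.tsv",
                    sep="\t", index=False, float_format="%.10g",
                )
                enrichment_tables[category] = table
        comparisons_report[comparison.name] = {
            "degs": degs,
            "summary": summary,
            "enrichment": enrichment_tables,
        }

    manifest = {
        "tagdge_version": _version,
        "config": {
            "references": config.references,
            "libraries": config.libraries,
            "comparisons": [
                {"name": c.name, "treated": c.treated, "control": c.control}
                for c in config.comparisons
            ],
            "annotations": config.annotations,
            "adaptor": config.adaptor,
            "quality_threshold": config.quality_threshold,
            "fdr_threshold": config.fdr_threshold,
            "lfc_threshold": config.lfc_threshold,
            "enrich_p_threshold": config.enrich_p_threshold,
            "both_strands": config.both_strands,
        },
        "input_sha256": input_hashes,
    }
    _write_json(manifest, out / "manifest.json")
    return {
        "table1": table1,
        "stats": stats,
        "libraries": libraries,
        "mapping": results,
        "comparisons": comparisons_report,
        "output_dir": str(out),
    }


def verify_run(run_dir: str | Path) -> list[str]:
    """Recompute report numbers from serialized intermediates; list diffs.

    Checks that each comparison's stored DEG summary matches a fresh
    :func:`summarize_degs` over the stored DEG table, and that stored
    enrichment p-values match fresh hypergeometric evaluation of the
    stored (dif, ref, n_query, n_background) columns. Returns an empty
    list when everything agrees.
    """
    from tagdge.enrichment import hypergeom_upper_tail

    run_dir = Path(run_dir)
    problems: list[str] = []
    for summary_path in sorted(run_dir.glob("*.summary.json")):
        name = summary_path.name.removesuffix(".summary.json")
        degs_path = run_dir / f"{name}.degs.tsv"
        if not degs_path.exists():
            continue  # library summaries have no DEG table
        with open(summary_path) as handle:
            stored = json.load(handle)
        fresh = summarize_degs(pd.read_csv(degs_path, sep="\t"))
        for key, value in fresh.items():
            if stored.get(key) != value:
                problems.append(
                    f"{name}: summary field {key!r} stored={stored.get(key)!r} "
                    f"recomputed={value!r}"
                )
        for enr_path in sorted(run_dir.glob(f"{name}.enrichment.*.tsv")):
            table = pd.read_csv(enr_path, sep="\t")
            for row in table.itertuples(index=False):
                p = hypergeom_upper_tail(
                    int(row.dif), int(row.ref), int(row.n_query),
                    int(row.n_background),
                )
                if abs(p - float(row.p_value)) > 1e-9 * max(p, 1e-300):
                    problems.append(
                        f"{enr_path.name}: term {row.term_id} stored "
                        f"p={row.p_value} recomputed p={p}"
                    )
    return problems
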