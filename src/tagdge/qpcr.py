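"""Relative quantification from qPCR Ct tables and DGE concordance.

Fold changes use the ddCt method: replicate Ct values are averaged on
the Ct scale, the target is normalized to the reference gene within each
condition, and the treated condition is normalized to the control. No
primer-efficiency correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tagdge.errors import FormatError, InputError


@dataclass
class QpcrRecord:
    """One gene x condition set of target and reference Ct replicates."""

    gene_id: str
    condition: str
    ct_target: list[float]
    ct_reference: list[float]

    def __post_init__(self) -> None:
        for name, values in (("ct_target", self.ct_target),
                             ("ct_reference", self.ct_reference)):
            if len(values) == 0:
                raise InputError(f"{name} replicate list is empty")
            if not all(0.0 < v < 50.0 for v in values):
                raise InputError(f"{name} values must lie in (0, 50)")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def ddct_fold_change(treated: QpcrRecord, control: QpcrRecord) -> float:
    """``2**-(dCt_treated - dCt_control)`` relative expression."""
    if treated.gene_id != control.gene_id:
        raise InputError(
            f"gene mismatch: {treated.gene_id!r} vs {control.gene_id!r}"
        )
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** -ddct)


def read_ct_table(path: str | Path) -> list[QpcrRecord]:
    """Load a TSV of per-replicate Ct rows into per-(gene, condition) records.

    Expected columns: gene_id, condition, replicate, ct_target,
    ct_reference.
    """
    frame = pd.read_csv(path, sep="\t")
    for column in ("gene_id", "condition", "ct_target", "ct_reference"):
        if column not in frame.columns:
            raise FormatError(f"Ct table {path} is missing column {column!r}")
    records = []
    for (gene_id, condition), group in frame.groupby(
        ["gene_id", "condition"], sort=True
    ):
        records.append(
            QpcrRecord(
                gene_id=str(gene_id),
                condition=str(condition),
                ct_target=[float(v) for v in group["ct_target"]],
                ct_reference=[float(v) for v in group["ct_reference"]],
            )
        )
    return records


def fold_changes_from_records(
    records: list[QpcrRecord], treated: str = "B", control: str = "A"
) -> dict[str, float]:
    """ddCt fold change per gene from a flat record list."""
    by_gene: dict[str, dict[str, QpcrRecord]] = {}
    for record in records:
        by_gene.setdefault(record.gene_id, {})[record.condition] = record
    folds = {}
    for gene_id, conditions in sorted(by_gene.items()):
        if treated in conditions and control in conditions:
            folds[gene_id] = ddct_fold_change(
                conditions[treated], conditions[control]
            )
    return folds


def concordance(qpcr_folds: dict[str, float], deg_table: pd.DataFrame) -> dict:
    """Direction-of-change agreement between qPCR folds and DGE calls.

    A shared gene is concordant iff sign(log2 qPCR fold) equals
    sign(DGE log2 ratio); a zero on either side counts as
    non-concordant.
    """
    dge = deg_table.set_index("gene_id")["log2_ratio"]
    shared = [g for g in qpcr_folds if g in dge.index]
    if not shared:
        raise InputError("no genes shared between qPCR folds and DEG table")
    rows = []
    for gene_id in shared:
        qpcr_log2 = math.log2(qpcr_folds[gene_id])
        dge_log2 = float(dge[gene_id])
        agree = (
            qpcr_log2 != 0.0
            and dge_log2 != 0.0
            and (qpcr_log2 > 0) == (dge_log2 > 0)
        )
        rows.append(
            {
                "gene_id": gene_id,
                "qpcr_log2_fold": qpcr_log2,
                "dge_log2_ratio": dge_log2,
                "concordant": agree,
            }
        )
    flags = pd.DataFrame(rows)
    return {
        "concordant": int(flags["concordant"].sum()),
        "total": len(flags),
        "flags": flags,
    }
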