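"""Hypergeometric over-representation analysis of DEG sets.

Terms (GO terms, pathway ids) are flat gene sets per category. The
background for a category is the set of genes with at least one
annotation in that category, matching the convention in which the "Ref"
column counts term-annotated genes. Raw upper-tail p <= threshold is the
significance filter; BH-adjusted values are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from tagdge.diffexpr import benjamini_hochberg
from tagdge.errors import DomainError, FormatError, InputError

DEFAULT_P_THRESHOLD = 0.05


@dataclass
class Annotation:
    """Category-keyed term -> gene-set map plus term descriptions."""

    terms: dict[str, dict[str, frozenset]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        return list(self.terms)

    def background(self, category: str) -> frozenset:
        term_map = self.terms.get(category, {})
        genes: set[str] = set()
        for members in term_map.values():
            genes |= members
        return frozenset(genes)


def annotation_from_frame(frame: pd.DataFrame) -> Annotation:
    required = ["gene_id", "term_id", "category"]
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"annotation table is missing column {column!r}")
    terms: dict[str, dict[str, set]] = {}
    descriptions: dict[str, str] = {}
    has_description = "description" in frame.columns
    for row in frame.itertuples(index=False):
        category = str(row.category)
        term = str(row.term_id)
        terms.setdefault(category, {}).setdefault(term, set()).add(str(row.gene_id))
        if has_description and isinstance(row.description, str):
            descriptions[term] = row.description
    frozen = {
        category: {term: frozenset(genes) for term, genes in term_map.items()}
        for category, term_map in terms.items()
    }
    return Annotation(frozen, descriptions)


def load_annotation(path: str | Path) -> Annotation:
    """Load a TSV with columns gene_id, term_id, category [, description]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return annotation_from_frame(frame)


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``k`` is the observed overlap, ``K`` the term size, ``n`` the query
    size, ``N`` the background size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError("require 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise DomainError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    logs = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, np.array([float(n)]))
    peak = logs.max()
    return float(min(1.0, math.exp(peak + math.log(np.exp(logs - peak).sum()))))


def enrich(
    deg_genes,
    annotation: Annotation,
    category: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Per-term over-representation table, sorted by ascending p-value.

    Columns: term_id, description, dif (DEGs in term), ref (background
    genes in term), n_query, n_background, p_value, adjusted_p,
    significant. Ties are ordered by term_id for determinism.
    """
    term_map = annotation.terms.get(category)
    if not term_map:
        raise InputError(f"empty background: no terms in category {category!r}")
    background = annotation.background(category)
    deg_set = frozenset(deg_genes)
    query = deg_set & background
    N = len(background)
    n = len(query)
    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id]
        ref = len(members)
        dif = len(deg_set & members)
        p = hypergeom_upper_tail(dif, ref, n, N)
        rows.append(
            {
                "term_id": term_id,
                "description": annotation.descriptions.get(term_id, ""),
                "dif": dif,
                "ref": ref,
                "n_query": n,
                "n_background": N,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["significant"] = table["p_value"] <= p_threshold
    table = table.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table
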