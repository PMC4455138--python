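"""TPM normalization and two-library exact differential expression.

The differential test is the exact conditional count test for two
libraries of known sizes: conditioning on the count ``x`` observed in
library A (clean total ``n1``), the count ``y`` in library B (clean
total ``n2``) follows

    P(Y = y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1)),

with ``r = n2 / n1``. The two-sided p-value is twice the smaller tail,
capped at 1. All tail sums are evaluated in log space via log-gamma.

Genes detected in at least one library are tested; p-values are adjusted
with Benjamini-Hochberg across exactly that set, and genes are called
up/down at the FDR and |log2 ratio| thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

from tagdge._util import round_half_up
from tagdge.errors import DomainError, InputError, UndefinedStatisticError
from tagdge.mapping import MappingResult

DEFAULT_FDR_THRESHOLD = 1e-3
DEFAULT_LFC_THRESHOLD = 1.0

# |log2 ratio| histogram bin edges for the DEG summary
FOLD_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 12.0, math.inf)
FOLD_BIN_LABELS = ("1-2", "2-3", "3-4", "4-12", ">=12")


@dataclass
class ExpressionProfile:
    """Per-gene unambiguous tag counts and TPM for one library."""

    library_id: str
    clean_total: int
    counts: pd.Series
    tpm: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.tpm.index):
            raise InputError("counts and tpm must share one gene index")


def compute_tpm(
    result: MappingResult | dict[str, int],
    clean_total: int,
    gene_universe=None,
    library_id: str | None = None,
) -> ExpressionProfile:
    """Scale unambiguous per-gene counts to tags-per-million clean tags.

    Genes in ``gene_universe`` missing from the counts get count 0 and
    TPM 0; by default the universe is the set of counted genes.
    """
    if clean_total <= 0:
        raise DomainError("clean_total must be positive for TPM normalization")
    if isinstance(result, MappingResult):
        gene_counts = result.gene_counts
        library_id = library_id or result.library_id
    else:
        gene_counts = dict(result)
        library_id = library_id or "library"
    if gene_universe is None:
        gene_universe = sorted(gene_counts)
    counts = pd.Series(
        [int(gene_counts.get(g, 0)) for g in gene_universe],
        index=pd.Index(gene_universe, name="gene_id"),
        dtype=np.int64,
    )
    tpm = counts / clean_total * 1e6
    return ExpressionProfile(library_id, int(clean_total), counts, tpm)


def _log_pmf(x: int, js: np.ndarray, log_r: float, log_1pr: float) -> np.ndarray:
    js = js.astype(float)
    return (
        js * log_r
        + gammaln(x + js + 1.0)
        - gammaln(x + 1.0)
        - gammaln(js + 1.0)
        - (x + js + 1.0) * log_1pr
    )


def _logsumexp(values: np.ndarray) -> float:
    peak = float(values.max())
    if peak == -math.inf:
        return -math.inf
    return peak + math.log(np.exp(values - peak).sum())


def _upper_tail(x: int, y: int, r: float, log_r: float, log_1pr: float) -> float:
    """Sum of P(Y = j | x) for j >= y, summed until the geometric-decay
    remainder bound is negligible relative to the accumulated mass."""
    chunk = 512
    start = y
    pieces: list[np.ndarray] = []
    while True:
        js = np.arange(start, start + chunk)
        pieces.append(_log_pmf(x, js, log_r, log_1pr))
        total = _logsumexp(np.concatenate(pieces))
        last_j = start + chunk - 1
        ratio = r * (x + last_j + 2) / ((last_j + 2) * (1.0 + r))
        if ratio < 1.0:
            remainder = pieces[-1][-1] + math.log(ratio / (1.0 - ratio))
            if remainder < total + math.log(1e-16):
                return float(math.exp(total))
        start += chunk


def _conditional_tails(x: int, y: int, r: float) -> tuple[float, float]:
    """(lower, upper) = (P(Y <= y | x), P(Y >= y | x)).

    The smaller tail is always the directly summed one; the larger is
    recovered from the complement, where absolute float error is
    harmless.
    """
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    pmf_y = math.exp(_log_pmf(x, np.array([y]), log_r, log_1pr)[0])
    mean = r * (x + 1.0)
    if y <= mean:
        lower = math.exp(_logsumexp(_log_pmf(x, np.arange(0, y + 1), log_r, log_1pr)))
        upper = 1.0 - lower + pmf_y
    else:
        upper = _upper_tail(x, y, r, log_r, log_1pr)
        lower = 1.0 - upper + pmf_y
    return min(lower, 1.0), min(upper, 1.0)


def exact_count_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for count ``x`` in library A vs ``y`` in B.

    ``n1`` and ``n2`` are the clean-tag library sizes. Returns
    ``min(1, 2 * min(lower tail, upper tail))``.
    """
    if x < 0 or y < 0:
        raise DomainError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise DomainError("library sizes must be positive")
    lower, upper = _conditional_tails(int(x), int(y), n2 / n1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_degs(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Exact-test DEG table for two expression profiles.

    Genes with zero counts in both libraries are excluded. For the log2
    ratio, a zero-count library's TPM is floored at the TPM of a single
    tag (``1e6 / clean_total``), keeping ratios finite and depth-aware.
    Returns a frame with columns gene_id, count_a, count_b, tpm_a,
    tpm_b, log2_ratio, p_value, fdr, status (``up``/``down``/``ns``).
    """
    if set(profile_a.counts.index) != set(profile_b.counts.index):
        raise InputError("profiles cover different gene universes")
    b = profile_b.counts.reindex(profile_a.counts.index)
    a = profile_a.counts
    tested = (a > 0) | (b > 0)
    genes = a.index[tested]
    xs = a[tested].to_numpy()
    ys = b[tested].to_numpy()

    floor_a = 1e6 / profile_a.clean_total
    floor_b = 1e6 / profile_b.clean_total
    tpm_a = profile_a.tpm[tested].to_numpy()
    tpm_b = profile_b.tpm.reindex(profile_a.tpm.index)[tested].to_numpy()
    ratio_a = np.where(xs > 0, tpm_a, floor_a)
    ratio_b = np.where(ys > 0, tpm_b, floor_b)
    log2_ratio = np.log2(ratio_b / ratio_a)

    cache: dict[tuple[int, int], float] = {}
    n1, n2 = profile_a.clean_total, profile_b.clean_total
    p_values = np.empty(len(genes))
    for i, (x, y) in enumerate(zip(xs, ys)):
        key = (int(x), int(y))
        if key not in cache:
            cache[key] = exact_count_pvalue(key[0], key[1], n1, n2)
        p_values[i] = cache[key]
    fdr = benjamini_hochberg(p_values)

    status = np.full(len(genes), "ns", dtype=object)
    significant = fdr < fdr_threshold
    status[significant & (log2_ratio >= lfc_threshold)] = "up"
    status[significant & (log2_ratio <= -lfc_threshold)] = "down"
    return pd.DataFrame(
        {
            "gene_id": genes,
            "count_a": xs,
            "count_b": ys,
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2_ratio": log2_ratio,
            "p_value": p_values,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)


def summarize_degs(table: pd.DataFrame) -> dict:
    """Up/down counts and |log2 ratio| fold-change bins among DEGs.

    Percentages are half-up rounded to one decimal; the ``1-4``
    aggregate bin mirrors the "one- to four-fold" report convention
    (|log2 ratio| in [1, 4)). An empty DEG set reports 0.0 percentages
    with ``percentages_defined`` False.
    """
    degs = table[table["status"] != "ns"]
    n_deg = len(degs)
    n_up = int((degs["status"] == "up").sum())
    n_down = int((degs["status"] == "down").sum())
    defined = n_deg > 0

    abs_ratio = degs["log2_ratio"].abs().to_numpy()
    bin_counts = {}
    bin_pcts = {}
    for label, lo, hi in zip(FOLD_BIN_LABELS, FOLD_BIN_EDGES, FOLD_BIN_EDGES[1:]):
        count = int(((abs_ratio >= lo) & (abs_ratio < hi)).sum())
        bin_counts[label] = count
        bin_pcts[label] = round_half_up(100.0 * count / n_deg, 1) if defined else 0.0
    n_1_4 = int(((abs_ratio >= 1.0) & (abs_ratio < 4.0)).sum())
    return {
        "n_deg": n_deg,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round_half_up(100.0 * n_up / n_deg, 1) if defined else 0.0,
        "pct_down": round_half_up(100.0 * n_down / n_deg, 1) if defined else 0.0,
        "fold_bin_counts": bin_counts,
        "fold_bin_pcts": bin_pcts,
        "n_1_4": n_1_4,
        "pct_1_4": round_half_up(100.0 * n_1_4 / n_deg, 1) if defined else 0.0,
        "percentages_defined": defined,
    }


def pearson_correlation(
    profile_a: ExpressionProfile, profile_b: ExpressionProfile
) -> float:
    """Pearson r over ``log2(tpm + 1)`` for genes detected in either library."""
    if set(profile_a.counts.index) != set(profile_b.counts.index):
        raise InputError("profiles cover different gene universes")
    b_counts = profile_b.counts.reindex(profile_a.counts.index)
    mask = (profile_a.counts > 0) | (b_counts > 0)
    if int(mask.sum()) < 2:
        raise UndefinedStatisticError("fewer than 2 detected genes")
    va = np.log2(profile_a.tpm[mask].to_numpy() + 1.0)
    vb = np.log2(profile_b.tpm.reindex(profile_a.tpm.index)[mask].to_numpy() + 1.0)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedStatisticError("zero variance in log-TPM values")
    return float(pearsonr(va, vb).statistic)
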