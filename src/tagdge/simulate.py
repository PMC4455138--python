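"""Synthetic data generation for the tag-DGE pipeline.

Generates reference transcriptomes (every gene guaranteed to carry an
anchored tag site), ground-truth expression tables with planted fold
changes, raw 21-nt tag libraries with substitution noise and adaptor
artifacts, gene->term annotation tables with optional planted
enrichment, and qPCR Ct tables consistent with the planted truth.

Every generator draws from a single seeded generator derived from
``(config.seed, operation stream)``, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tagdge.errors import ConfigurationError, InputError
from tagdge.mapping import canonical_tag
from tagdge.reads import RawReads
from tagdge.reference import ReferenceTranscriptome
from tagdge.tags import DEFAULT_ADAPTOR, TAG_LENGTH

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

# independent substreams per operation
_STREAM_TRANSCRIPTOME = 0
_STREAM_TRUTH = 1
_STREAM_LIBRARY = 2
_STREAM_ANNOTATION = 3
_STREAM_QPCR = 4

_ERROR_CHUNK = 1 << 18  # reads per substitution-noise chunk


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``lfc_magnitude_range`` bounds the planted |log2 fold change|; its
    lower bound doubles as the planted-effect threshold, so a gene is
    differentially expressed iff its |log2_fc| reaches it.
    """

    n_genes: int
    gene_length_range: tuple[int, int] = (200, 400)
    de_fraction: float = 0.0
    frac_up: float = 0.5
    lfc_magnitude_range: tuple[float, float] = (1.0, 4.0)
    library_depth: int = 100_000
    error_rate: float = 0.0
    adaptor_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    baseline_log2_mu: float = 0.0
    baseline_log2_sigma: float = 1.5
    adaptor: str = DEFAULT_ADAPTOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not (25 <= lo <= hi):
            raise ConfigurationError(
                "gene_length_range must satisfy 25 <= lo <= hi"
            )
        for name in ("de_fraction", "frac_up", "error_rate",
                     "adaptor_fraction", "low_quality_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        flo, fhi = self.lfc_magnitude_range
        if not (0.0 < flo <= fhi):
            raise ConfigurationError(
                "lfc_magnitude_range must satisfy 0 < lo <= hi"
            )
        if self.library_depth < 0:
            raise ConfigurationError("library_depth must be >= 0")
        if self.baseline_log2_sigma <= 0:
            raise ConfigurationError("baseline_log2_sigma must be > 0")
        if len(self.adaptor) != TAG_LENGTH or not set(self.adaptor) <= set("ACGT"):
            raise ConfigurationError("adaptor must be a 21-nt ACGT sequence")


def _rng(config: SimulationConfig, stream: int, label: str = "") -> np.random.Generator:
    entropy = [config.seed, stream]
    if label:
        entropy.append(zlib.crc32(label.encode()))
    return np.random.default_rng(entropy)


def generate_transcriptome(config: SimulationConfig) -> ReferenceTranscriptome:
    """Random ACGT genes, each with a planted CATG + 17 nt tag site."""
    rng = _rng(config, _STREAM_TRANSCRIPTOME)
    lo, hi = config.gene_length_range
    records: dict[str, str] = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        codes = _BASES[rng.integers(0, 4, size=length)]
        site = int(rng.integers(0, length - TAG_LENGTH + 1))
        codes[site : site + 4] = _BASES[[1, 0, 3, 2]]  # CATG
        records[f"g{i:05d}"] = codes.tobytes().decode()
    return ReferenceTranscriptome(records)


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table: baseline abundance, planted log2 fc, DE flag.

    Baselines are log-normal (``2**Normal(mu, sigma)``); exactly
    ``round(n_genes * de_fraction)`` genes are flagged DE, of which
    ``round(n_de * frac_up)`` get positive fold changes.
    """
    rng = _rng(config, _STREAM_TRUTH)
    n = config.n_genes
    baseline = 2.0 ** rng.normal(
        config.baseline_log2_mu, config.baseline_log2_sigma, size=n
    )
    log2_fc = np.zeros(n)
    n_de = round(n * config.de_fraction)
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_up = round(n_de * config.frac_up)
    flo, fhi = config.lfc_magnitude_range
    magnitudes = rng.uniform(flo, fhi, size=n_de)
    signs = np.where(np.arange(n_de) < n_up, 1.0, -1.0)
    log2_fc[de_idx] = signs * magnitudes
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "baseline_abundance": baseline,
            "log2_fc": log2_fc,
            "is_de": log2_fc != 0.0,
        }
    )


def _apply_substitutions(
    smat: np.ndarray, editable: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    """In-place i.i.d. per-base substitutions on editable rows."""
    n = smat.shape[0]
    for start in range(0, n, _ERROR_CHUNK):
        stop = min(start + _ERROR_CHUNK, n)
        block = smat[start:stop]
        mask = rng.random(block.shape) < rate
        mask &= editable[start:stop, None]
        n_hits = int(mask.sum())
        if n_hits == 0:
            continue
        old = _BASE_INDEX[block[mask]]
        shift = rng.integers(1, 4, size=n_hits)  # guarantees a real change
        block[mask] = _BASES[(old + shift) % 4]


def sample_tag_library(
    truth: pd.DataFrame,
    transcriptome: ReferenceTranscriptome,
    condition: str,
    config: SimulationConfig,
) -> RawReads:
    """Draw ``library_depth`` raw 21-nt reads for one condition.

    Condition "A" samples genes with probability proportional to the
    baseline abundance; condition "B" multiplies each abundance by
    ``2**log2_fc``. Informative reads are each gene's canonical tag;
    adaptor artifacts replace a Bernoulli(``adaptor_fraction``) subset,
    and substitution noise is applied to informative reads only.
    """
    if condition not in ("A", "B"):
        raise InputError(f"condition must be 'A' or 'B', got {condition!r}")
    missing = set(truth["gene_id"]) - set(transcriptome.gene_ids)
    if missing:
        raise InputError(
            f"truth genes absent from transcriptome: {sorted(missing)[:5]}"
        )
    rng = _rng(config, _STREAM_LIBRARY, condition)
    depth = config.library_depth
    if depth == 0:
        return RawReads(np.empty(0, dtype="S21"), np.empty(0, dtype="S21"))

    tag_rows = []
    for gene_id in truth["gene_id"]:
        tag = canonical_tag(transcriptome[gene_id])
        if tag is None:
            raise InputError(f"gene {gene_id} has no CATG+17 tag site")
        tag_rows.append(tag)
    tag_codes = np.frombuffer("".join(tag_rows).encode(), dtype=np.uint8)
    tag_codes = tag_codes.reshape(len(tag_rows), TAG_LENGTH)

    weights = truth["baseline_abundance"].to_numpy(dtype=float).copy()
    if condition == "B":
        weights *= 2.0 ** truth["log2_fc"].to_numpy(dtype=float)
    probs = weights / weights.sum()

    # multinomial + shuffle: same read-multiset law as i.i.d. draws, much faster
    per_gene = rng.multinomial(depth, probs)
    gene_idx = np.repeat(np.arange(len(tag_rows)), per_gene)
    rng.shuffle(gene_idx)
    smat = tag_codes[gene_idx].copy()

    adaptor_mask = rng.random(depth) < config.adaptor_fraction
    if config.error_rate > 0:
        _apply_substitutions(smat, ~adaptor_mask, config.error_rate, rng)
    if adaptor_mask.any():
        smat[adaptor_mask] = np.frombuffer(config.adaptor.encode(), dtype=np.uint8)

    lowq_mask = rng.random(depth) < config.low_quality_fraction
    quals = np.where(lowq_mask, np.bytes_(b"#" * TAG_LENGTH), np.bytes_(b"I" * TAG_LENGTH))
    sequences = np.frombuffer(smat.tobytes(), dtype="S21")
    return RawReads(sequences, quals.astype("S21"))


def generate_annotation(
    truth: pd.DataFrame,
    n_terms: int,
    planted_terms: list[str] | None = None,
    seed: int = 0,
    base_prob: float = 0.05,
    odds_multiplier: float = 10.0,
    category: str = "pathway",
) -> pd.DataFrame:
    """Random gene->term memberships with optional planted enrichment.

    Each gene joins each term independently with probability
    ``base_prob``; for planted terms, DE genes join with the base odds
    multiplied by ``odds_multiplier``, making enrichment recoverable.
    """
    planted_terms = list(planted_terms or [])
    term_ids = [f"T{i:04d}" for i in range(n_terms)]
    unknown = set(planted_terms) - set(term_ids)
    if unknown:
        raise InputError(f"planted terms outside term universe: {sorted(unknown)}")
    rng = np.random.default_rng([seed, _STREAM_ANNOTATION])
    if n_terms == 0:
        return pd.DataFrame(columns=["gene_id", "term_id", "category"])
    n = len(truth)
    is_de = truth["is_de"].to_numpy(dtype=bool)
    base_odds = base_prob / (1.0 - base_prob)
    boosted = (base_odds * odds_multiplier) / (1.0 + base_odds * odds_multiplier)
    prob = np.full((n, n_terms), base_prob)
    planted_cols = [term_ids.index(t) for t in planted_terms]
    for col in planted_cols:
        prob[is_de, col] = boosted
    member = rng.random((n, n_terms)) < prob
    gene_pos, term_pos = np.nonzero(member)
    genes = truth["gene_id"].to_numpy()
    return pd.DataFrame(
        {
            "gene_id": genes[gene_pos],
            "term_id": [term_ids[j] for j in term_pos],
            "category": category,
        }
    )


def generate_ct_table(
    truth: pd.DataFrame,
    gene_ids: list[str],
    seed: int = 0,
    base_ct: float = 24.0,
    reference_ct: float = 16.0,
    replicates: int = 3,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table consistent with the planted fold changes.

    For each requested gene, condition "B" target Ct is shifted by
    ``-log2_fc`` relative to condition "A" (one cycle per doubling), so
    the ddCt fold change recovers ``2**log2_fc`` up to replicate noise.
    """
    rng = np.random.default_rng([seed, _STREAM_QPCR])
    lookup = truth.set_index("gene_id")["log2_fc"]
    missing = [g for g in gene_ids if g not in lookup.index]
    if missing:
        raise InputError(f"genes absent from truth: {missing[:5]}")
    rows = []
    for gene_id in gene_ids:
        lfc = float(lookup[gene_id])
        for condition, shift in (("A", 0.0), ("B", -lfc)):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": base_ct + shift + rng.normal(0.0, noise_sd),
                        "ct_reference": reference_ct + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
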