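"""Shared fixtures: a small planted-DE synthetic dataset built once."""

from __future__ import annotations

import pytest

from tagdge import (
    SimulationConfig,
    build_tag_index,
    compute_tpm,
    extract_clean_tags,
    generate_transcriptome,
    generate_truth,
    map_tags,
    sample_tag_library,
)


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=300,
        gene_length_range=(150, 300),
        de_fraction=0.1,
        frac_up=0.8,
        lfc_magnitude_range=(2.0, 4.0),
        library_depth=60_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def transcriptome(planted_config):
    return generate_transcriptome(planted_config)


@pytest.fixture(scope="session")
def truth(planted_config):
    return generate_truth(planted_config)


@pytest.fixture(scope="session")
def tag_index(transcriptome):
    return build_tag_index(transcriptome)


@pytest.fixture(scope="session")
def libraries(planted_config, transcriptome, truth):
    libs = {}
    for condition in ("A", "B"):
        reads = sample_tag_library(truth, transcriptome, condition, planted_config)
        libs[condition] = extract_clean_tags(reads, library_id=condition)
    return libs


@pytest.fixture(scope="session")
def mapping_results(libraries, tag_index):
    return {c: map_tags(lib, tag_index) for c, lib in libraries.items()}


@pytest.fixture(scope="session")
def profiles(mapping_results, libraries, transcriptome):
    return {
        c: compute_tpm(
            mapping_results[c],
            libraries[c].clean_total,
            gene_universe=transcriptome.gene_ids,
        )
        for c in ("A", "B")
    }
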