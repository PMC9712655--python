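"""Shared fixtures: a small synthetic library with a planted triazine
effect, its curated structures and descriptor matrices.

Session scope amortizes descriptor computation across test modules.
"""

import pytest

from steroidqsar.curation import curate_library
from steroidqsar.descriptors import (
    compute_descriptor_matrix,
    select_descriptors,
    standardize_matrix,
)
from steroidqsar.synthetic import SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_chemicals=300, seed=11, motif_effects={"triazine": 8}, label_noise=0.0
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return generate_library(small_config)


@pytest.fixture(scope="session")
def small_curated(small_library):
    curated, rejections = curate_library(small_library.records)
    assert rejections == {}
    return curated


@pytest.fixture(scope="session")
def small_matrix(small_curated):
    return compute_descriptor_matrix(small_curated)


@pytest.fixture(scope="session")
def small_selected(small_matrix):
    selected, _ = select_descriptors(small_matrix, seed=0)
    return selected


@pytest.fixture(scope="session")
def small_scaled(small_selected):
    scaled, _ = standardize_matrix(small_selected)
    return scaled


@pytest.fixture(scope="session")
def small_labels(small_library):
    return {r.id: r.labels["E2up"] for r in small_library.records}
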