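"""Descriptor computation and the two-stage selection rules."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from steroidqsar.curation import standardize_structure
from steroidqsar.descriptors import (
    DescriptorMatrix,
    aromatic_bond_count,
    chi6_chain,
    compute_descriptor_matrix,
    correlation_cluster_select,
    merge_external_descriptors,
    remove_uninformative,
    select_descriptors,
    standardize_matrix,
)
from steroidqsar.errors import InputError, PipelineError


def _matrix(data: dict) -> DescriptorMatrix:
    df = pd.DataFrame(data, index=[f"c{i}" for i in range(len(next(iter(data.values()))))])
    return DescriptorMatrix(values=df.astype(float))


def test_named_descriptor_values():
    benzene = Chem.MolFromSmiles("c1ccccc1")
    ethane = Chem.MolFromSmiles("CC")
    assert aromatic_bond_count(benzene) == 6
    assert aromatic_bond_count(ethane) == 0
    assert chi6_chain(ethane) == 0.0
    assert chi6_chain(benzene) == pytest.approx(0.125)  # (1/sqrt 2)^6


def test_matrix_has_no_missing_values(small_matrix):
    assert not small_matrix.values.isna().any().any()
    assert np.isfinite(small_matrix.values.to_numpy()).all()
    assert {"ArBondCount", "Chi6ch"} <= set(small_matrix.names)


def test_compute_matrix_named_columns_match_structures():
    curated = [standardize_structure(s, id=i) for i, s in [("benzene", "c1ccccc1"), ("ethane", "CC")]]
    matrix = compute_descriptor_matrix(curated)
    assert matrix.values.loc["benzene", "ArBondCount"] == 6
    assert matrix.values.loc["ethane", "ArBondCount"] == 0
    assert matrix.values.loc["ethane", "Chi6ch"] == 0


def test_remove_uninformative_boundaries():
    values = {
        "constant": [5.0] * 100,
        "nearly": [5.0] * 91 + [1.0] * 9,          # modal fraction 0.91 > 0.90 -> dropped
        "boundary": [5.0] * 90 + list(range(100, 110)),  # exactly 0.90 -> retained
        "informative": list(range(100)),
    }
    kept, report = remove_uninformative(_matrix(values))
    assert report.dropped_null_variance == ["constant"]
    assert report.dropped_near_constant == ["nearly"]
    assert set(kept.names) == {"boundary", "informative"}


def test_remove_uninformative_can_empty_the_matrix():
    with pytest.raises(PipelineError):
        remove_uninformative(_matrix({"constant": [1.0] * 10}))


def test_correlation_clustering_rules():
    rng = np.random.default_rng(0)
    base = rng.normal(size=200)
    other = rng.normal(size=200)
    m = _matrix(
        {
            "a": base,
            "a_copy": base,                        # r = 1 with a
            "a_noisy": base + rng.normal(0, 0.05, 200),  # r > 0.9 with a
            "b": other,                            # independent
        }
    )
    kept, report = correlation_cluster_select(m, seed=1)
    cluster_sizes = sorted(len(c["members"]) for c in report.correlation_clusters)
    assert cluster_sizes == [1, 3]
    assert len(kept.names) == 2 and "b" in kept.names


def test_uncorrelated_columns_all_retained():
    rng = np.random.default_rng(3)
    m = _matrix({f"x{i}": rng.normal(size=100) for i in range(5)})
    kept, _ = correlation_cluster_select(m, seed=0)
    assert kept.names == m.names


def test_selection_is_deterministic_and_idempotent(small_matrix):
    first, _ = select_descriptors(small_matrix, seed=4)
    second, _ = select_descriptors(small_matrix, seed=4)
    assert first.names == second.names
    again, report = select_descriptors(first, seed=4)
    assert again.names == first.names
    assert all(len(c["members"]) == 1 for c in report.correlation_clusters)


def test_merge_external_descriptors():
    m = _matrix({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    ids = list(m.values.index)
    empty = pd.DataFrame(index=ids)
    assert merge_external_descriptors(m, empty).names == m.names

    table = pd.DataFrame(
        np.arange(3 * 19, dtype=float).reshape(3, 19),
        index=ids,
        columns=[f"ext{i}" for i in range(19)],
    )
    merged = merge_external_descriptors(m, table)
    assert len(merged.names) == len(m.names) + 19
    assert merged.provenance["ext0"] == "external"

    with pytest.raises(InputError, match="unknown"):
        merge_external_descriptors(m, table.rename(index={ids[0]: "stranger"}))
    with pytest.raises(InputError, match="collide"):
        merge_external_descriptors(m, table.rename(columns={"ext0": "a"}))


def test_standardize_matrix_zscores(small_selected):
    scaled, scaler = standardize_matrix(small_selected)
    assert np.allclose(scaled.mean(), 0, atol=1e-9)
    assert np.allclose(scaled.std(ddof=0), 1, atol=1e-9)
    rescaled, _ = standardize_matrix(small_selected, scaler=scaler)
    assert np.allclose(rescaled.to_numpy(), scaled.to_numpy())
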