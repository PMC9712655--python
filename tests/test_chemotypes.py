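"""Chemotype matching, chi-squared enrichment and co-occurrence networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steroidqsar.chemotypes import (
    BUILTIN_CHEMOTYPES,
    ChemotypeMatrix,
    chemotype_enrichment,
    cooccurrence_network,
    load_chemotype_matrix,
    match_builtin_chemotypes,
    mean_chemotypes_per_chemical,
)
from steroidqsar.curation import standardize_structure
from steroidqsar.errors import InputError


def _curated(pairs):
    return [standardize_structure(smiles, id=cid) for cid, smiles in pairs]


def test_builtin_matching_examples():
    matrix = match_builtin_chemotypes(
        _curated(
            [
                ("phenol", "Oc1ccccc1"),
                ("atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1"),
                ("ethane", "CC"),
            ]
        )
    )
    df = matrix.values
    assert df.loc["phenol", "ring.aromatic_benzene"] == 1
    assert df.loc["phenol", "bond.COH_alcohol_aromatic_phenol"] == 1
    assert df.loc["phenol", "ring.hetero_6_N_triazine_135"] == 0
    assert df.loc["atrazine", "ring.hetero_6_N_triazine_135"] == 1
    assert (df.loc["ethane"] == 0).all()


def test_load_chemotype_matrix_validation(tmp_path):
    good = tmp_path / "good.tsv"
    good.write_text("DTXSID\tct_a\tct_b\nid1\t1\t0\nid2\t0\t0\nid3\t1\t1\n")
    matrix = load_chemotype_matrix(good)
    assert matrix.values.shape == (3, 2) and matrix.source == "external_file"

    bad_cell = tmp_path / "bad.tsv"
    bad_cell.write_text("DTXSID\tct_a\nid1\t2\n")
    with pytest.raises(InputError, match="non-binary"):
        load_chemotype_matrix(bad_cell)

    dup = tmp_path / "dup.tsv"
    dup.write_text("DTXSID\tct_a\nid1\t1\nid1\t0\n")
    with pytest.raises(InputError, match="duplicate"):
        load_chemotype_matrix(dup)


def _matrix_from_counts(n_active, n_other, a_has, o_has, name="ct"):
    ids = [f"a{i}" for i in range(n_active)] + [f"o{i}" for i in range(n_other)]
    flags = (
        [1] * a_has + [0] * (n_active - a_has) + [1] * o_has + [0] * (n_other - o_has)
    )
    values = pd.DataFrame({name: flags}, index=ids)
    return ChemotypeMatrix(values=values), [f"a{i}" for i in range(n_active)]


def test_chi2_matches_bruteforce_oracle():
    """Chi-squared statistic equals explicit observed/expected arithmetic."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_active = int(rng.integers(20, 80))
        n_other = int(rng.integers(50, 300))
        a_has = int(rng.integers(1, n_active))
        o_has = int(rng.integers(1, n_other))
        matrix, actives = _matrix_from_counts(n_active, n_other, a_has, o_has)
        row = chemotype_enrichment(matrix, actives).iloc[0]

        observed = np.array(
            [[a_has, n_active - a_has], [o_has, n_other - o_has]], dtype=float
        )
        total = observed.sum()
        expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert row["chi2"] == pytest.approx(chi2, abs=1e-9)
        assert row["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)


def test_strong_enrichment_is_highly_significant():
    # 11 of 182 actives carry the chemotype vs 19 of 1925 chemicals overall
    matrix, actives = _matrix_from_counts(182, 1925 - 182, 11, 8)
    row = chemotype_enrichment(matrix, actives).iloc[0]
    assert row["p_value"] < 0.001 and row["tier"] == "***"


def test_equal_prevalence_is_not_significant():
    matrix, actives = _matrix_from_counts(100, 100, 30, 30)
    row = chemotype_enrichment(matrix, actives).iloc[0]
    assert row["tier"] == "-"


def test_absent_chemotype_is_untestable():
    matrix, actives = _matrix_from_counts(50, 100, 0, 0)
    row = chemotype_enrichment(matrix, actives).iloc[0]
    assert row["untestable"] and np.isnan(row["p_value"]) and row["tier"] == "-"


def test_enrichment_input_validation():
    matrix, actives = _matrix_from_counts(10, 20, 5, 5)
    with pytest.raises(InputError):
        chemotype_enrichment(matrix, [])
    with pytest.raises(InputError):
        chemotype_enrichment(matrix, ["stranger"])


def test_reported_flag_follows_active_prevalence():
    high, actives = _matrix_from_counts(100, 500, 30, 30)
    assert bool(chemotype_enrichment(high, actives).iloc[0]["reported"])
    low, actives = _matrix_from_counts(100, 500, 10, 30)
    assert not bool(chemotype_enrichment(low, actives).iloc[0]["reported"])


def test_cooccurrence_network_edges_count_shared_actives():
    ids = [f"a{i}" for i in range(60)] + [f"o{i}" for i in range(440)]
    values = pd.DataFrame(0, index=ids, columns=["ct_x", "ct_y", "ct_z"])
    actives = [f"a{i}" for i in range(60)]
    values.loc[actives[:55], "ct_x"] = 1
    values.loc[actives[:50], "ct_y"] = 1  # 50 actives share x and y
    matrix = ChemotypeMatrix(values=values)
    enrichment = chemotype_enrichment(matrix, actives)
    graph = cooccurrence_network(matrix, enrichment, actives, p_cutoff=0.01)
    assert set(graph.nodes) == {"ct_x", "ct_y"}  # ct_z untestable/absent
    assert graph.edges[("ct_x", "ct_y")]["weight"] == 50
    assert graph.nodes["ct_x"]["count_active"] == 55
    # edge weight never exceeds either endpoint count
    for a, b, w in graph.edges(data="weight"):
        assert w <= min(graph.nodes[a]["count_active"], graph.nodes[b]["count_active"])


def test_empty_network_without_significant_chemotypes():
    matrix, actives = _matrix_from_counts(100, 100, 30, 30)
    enrichment = chemotype_enrichment(matrix, actives)
    graph = cooccurrence_network(matrix, enrichment, actives)
    assert graph.number_of_nodes() == 0


def test_mean_chemotypes_per_chemical(small_curated):
    matrix = match_builtin_chemotypes(small_curated)
    mean = mean_chemotypes_per_chemical(matrix)
    assert 0 < mean < len(BUILTIN_CHEMOTYPES)
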