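"""Chemotype matrices, chi-squared activity enrichment, and co-occurrence
networks of significant chemotypes.

A chemotype matrix is a binary chemicals x features table: each feature is a
toxicologically relevant substructure (benzene ring, phenol, aromatic amine,
triazine ring, aryl halide, thio/dithiophosphate, sulfonyl, ...).  Matrices
can be loaded from an external batch-search export (e.g. a ToxPrint TSV) or
computed with the built-in SMARTS vocabulary below.

Enrichment of each chemotype in an active set against the full tested
background uses a two-sided Pearson chi-squared test (no continuity
correction) on the 2x2 table (active vs non-active) x (has vs lacks the
chemotype).  Raw p-value tiers follow the conventional cutpoints
(*** < 0.001, ** < 0.01, * < 0.05); a Benjamini-Hochberg column is emitted
alongside for transparency but does not drive the tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .curation import CuratedStructure
from .errors import InputError

# Built-in chemotype vocabulary (name -> SMARTS), mirroring the families a
# ToxPrint-style profile flags on steroidogenesis-active chemicals.
BUILTIN_CHEMOTYPES: dict[str, str] = {
    "ring.aromatic_benzene": "c1ccccc1",
    "bond.COH_alcohol_aromatic_phenol": "[OX2H][c]",
    "bond.CN_amine_pri_aromatic": "[NX3;H2][c]",
    "bond.CN_amine_aromatic_generic": "[NX3][c]",
    "bond.CN_amine_sec_generic": "[NX3;H1]([#6])[#6]",
    "bond.CN_amine_aromatic_benzidine": "[NX3;H2]c1ccc(-c2ccc([NX3;H2])cc2)cc1",
    "ring.hetero_6_N_triazine_135": "c1ncncn1",
    "bond.CX_halide_aromatic": "[F,Cl,Br,I][c]",
    "bond.PS_thio_dithiophosphate": "[PX4](=[SX1])",
    "chain.aromaticAlkane_PhC1": "[c;$(c1ccccc1)][CX4]",
    "ring.fused_66_naphthalene": "c1ccc2ccccc2c1",
    "bond.SO_sulfonyl": "[#16X4](=[OX1])(=[OX1])",
}

# Defining chemotype for each synthetic planted motif (used to check
# enrichment recovery on generated libraries).
MOTIF_DEFINING_CHEMOTYPE: dict[str, str] = {
    "triazine": "ring.hetero_6_N_triazine_135",
    "phenol": "bond.COH_alcohol_aromatic_phenol",
    "aromatic_amine": "bond.CN_amine_pri_aromatic",
    "biphenyl_diamine": "bond.CN_amine_aromatic_benzidine",
    "phosphorodithioate": "bond.PS_thio_dithiophosphate",
    "aryl_halide": "bond.CX_halide_aromatic",
}

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
REPORTED_PREVALENCE = 0.20  # "most represented" flag: present in >20% of actives


@dataclass
class ChemotypeMatrix:
    """Binary chemicals x chemotypes table."""

    values: pd.DataFrame  # index: chemical ids; columns: chemotype names; 0/1
    source: str = "builtin_smarts"

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


def load_chemotype_matrix(path, id_column: str | None = None) -> ChemotypeMatrix:
    """Load a chemotype matrix from a TSV/CSV batch export.

    The first column (or ``id_column``) holds chemical ids; every remaining
    column must be binary 0/1.  Non-binary cells and duplicate ids are
    reported as input errors with their location.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected an id column plus chemotype columns")
    id_col = id_column or df.columns[0]
    if id_col not in df.columns:
        raise InputError(f"{path}: id column {id_col!r} not found")
    dup = df[id_col][df[id_col].duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicate chemical id {dup.iloc[0]!r}")
    df = df.set_index(id_col)
    for col in df.columns:
        bad = ~df[col].isin([0, 1, "0", "1"])
        if bad.any():
            row = df.index[bad.argmax()]
            raise InputError(
                f"{path}: non-binary value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
    return ChemotypeMatrix(values=df.astype(int), source="external_file")


def match_builtin_chemotypes(
    curated: Sequence[CuratedStructure],
    vocabulary: dict[str, str] | None = None,
) -> ChemotypeMatrix:
    """Substructure-match the built-in chemotype vocabulary over a library."""
    vocab = vocabulary or BUILTIN_CHEMOTYPES
    patterns = {name: Chem.MolFromSmarts(smarts) for name, smarts in vocab.items()}
    rows = {}
    for entry in curated:
        mol = Chem.MolFromSmiles(entry.smiles_std)
        if mol is None:
            raise InputError(f"chemical {entry.id!r} is not QSAR-ready")
        rows[entry.id] = {
            name: int(mol.HasSubstructMatch(pat)) for name, pat in patterns.items()
        }
    return ChemotypeMatrix(values=pd.DataFrame.from_dict(rows, orient="index"))


def _tier(p: float) -> str:
    for cut, stars in SIGNIFICANCE_TIERS:
        if p < cut:
            return stars
    return "-"


def chemotype_enrichment(
    matrix: ChemotypeMatrix,
    active_ids: Iterable[str],
    background_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-chemotype chi-squared enrichment of an active set vs background.

    The background is the full tested set (actives included); each chemotype
    is tested on the 2x2 table (active vs non-active) x (has vs lacks).
    Returns one row per chemotype ordered by ascending p-value (untestable
    chemotypes — absent or ubiquitous — last, flagged ``untestable``), with
    counts, prevalences, the chi2 statistic, raw and BH-adjusted p-values,
    the significance tier and the >20%-of-actives ``reported`` flag.
    """
    active = list(dict.fromkeys(active_ids))
    background = list(dict.fromkeys(background_ids)) if background_ids is not None else matrix.ids
    if not active:
        raise InputError("active set must be non-empty")
    if not set(active) <= set(background):
        raise InputError("active ids must be a subset of the background ids")
    missing = set(background) - set(matrix.ids)
    if missing:
        raise InputError(f"chemotype matrix misses ids: {sorted(missing)[:5]}")

    df = matrix.values.loc[background]
    is_active = df.index.isin(set(active))
    n_active, n_other = int(is_active.sum()), int((~is_active).sum())
    rows = []
    for name in df.columns:
        has = df[name].to_numpy(dtype=bool)
        a_has = int((has & is_active).sum())
        o_has = int((has & ~is_active).sum())
        table = np.array(
            [[a_has, n_active - a_has], [o_has, n_other - o_has]], dtype=float
        )
        untestable = table[:, 0].sum() == 0 or table[:, 1].sum() == 0 or n_other == 0
        if untestable:
            chi2, p, expected_min = np.nan, np.nan, np.nan
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            expected_min = float(expected.min())
        rows.append(
            {
                "chemotype": name,
                "count_active": a_has,
                "prevalence_active": a_has / n_active,
                "count_background": a_has + o_has,
                "prevalence_background": (a_has + o_has) / (n_active + n_other),
                "chi2": chi2,
                "p_value": p,
                "tier": _tier(p) if not untestable else "-",
                "reported": a_has / n_active > REPORTED_PREVALENCE,
                "low_expected_count": bool(expected_min < 5) if not untestable else False,
                "untestable": bool(untestable),
            }
        )
    result = pd.DataFrame(rows)
    testable = ~result["untestable"]
    result["p_bh"] = np.nan
    if testable.any():
        p_raw = result.loc[testable, "p_value"].to_numpy()
        order = np.argsort(p_raw)
        m = len(p_raw)
        adj = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running = min(running, p_raw[idx] * m / rank)
            adj[idx] = running
        result.loc[testable, "p_bh"] = adj
    result = result.sort_values(
        ["untestable", "p_value"], ascending=[True, True], ignore_index=True
    )
    return result


def cooccurrence_network(
    matrix: ChemotypeMatrix,
    enrichment: pd.DataFrame,
    active_ids: Iterable[str],
    p_cutoff: float = 0.01,
) -> nx.Graph:
    """Network of significant chemotypes linked by co-occurrence in actives.

    Nodes are chemotypes with p < ``p_cutoff`` (annotated with their active
    counts); an edge's weight is the number of active chemicals containing
    both chemotypes; zero-weight edges are omitted.
    """
    active = [i for i in dict.fromkeys(active_ids)]
    significant = enrichment[
        (~enrichment["untestable"]) & (enrichment["p_value"] < p_cutoff)
    ]
    graph = nx.Graph()
    sub = matrix.values.loc[[i for i in active if i in matrix.values.index]]
    for _, row in significant.iterrows():
        graph.add_node(row["chemotype"], count_active=int(row["count_active"]))
    names = list(significant["chemotype"])
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            weight = int((sub[a].astype(bool) & sub[b].astype(bool)).sum())
            if weight > 0:
                graph.add_edge(a, b, weight=weight)
    return graph


def mean_chemotypes_per_chemical(matrix: ChemotypeMatrix) -> float:
    """Average number of chemotypes present per chemical."""
    return float(matrix.values.sum(axis=1).mean())
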