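"""1D/2D molecular descriptors and two-stage descriptor selection.

The descriptor block covers the usual 2D families — constitutional counts,
topological and connectivity (chi/kappa) indices, E-state sums, Burden
eigenvalue (BCUT) descriptors, information content, MOE-type surface/charge
(VSA) descriptors and drug-likeness (QED) — computed with RDKit, plus two
named composition descriptors used throughout the analysis: the aromatic
bond count (``ArBondCount``) and the simple chi connectivity index over
six-membered rings (``Chi6ch``).

Selection proceeds in two stages: (1) drop uninformative columns (zero
variance, or one value covering more than 90% of the chemicals); (2) cluster
the survivors by absolute pairwise Pearson correlation > 0.9 (connected
components of the correlation graph) and keep one randomly chosen
representative per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RD

from .curation import CuratedStructure
from .errors import InputError, PipelineError

_MAX_FAILED_FRACTION = 0.10  # drop a descriptor if it fails on >10% of chemicals


@dataclass
class DescriptorMatrix:
    """Chemicals x descriptors table with per-column provenance.

    ``values`` is a pandas DataFrame indexed by chemical id; ``provenance``
    maps each descriptor name to ``"computed"`` or ``"external"``.
    """

    values: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SelectionReport:
    dropped_null_variance: list[str] = field(default_factory=list)
    dropped_near_constant: list[str] = field(default_factory=list)
    correlation_clusters: list[dict] = field(default_factory=list)
    threshold: float = 0.9
    near_constant_fraction: float = 0.90
    seed: int = 0


def aromatic_bond_count(mol: Chem.Mol) -> int:
    """Number of aromatic bonds (benzene -> 6, ethane -> 0)."""
    return sum(1 for bond in mol.GetBonds() if bond.GetIsAromatic())


def chi6_chain(mol: Chem.Mol) -> float:
    """Simple connectivity chi index over six-membered rings.

    For each ring of size 6, the product over ring atoms of 1/sqrt(delta)
    where delta is the heavy-atom degree; benzene scores (1/sqrt(2))^6 = 0.125.
    """
    total = 0.0
    for ring in Chem.GetSymmSSSR(mol):
        if len(ring) != 6:
            continue
        prod = 1.0
        for idx in ring:
            delta = mol.GetAtomWithIdx(idx).GetDegree()
            prod *= 1.0 / math.sqrt(delta)
        total += prod
    return total


# raw Ipc grows super-exponentially with size and overflows downstream
# float32 learners; the size-normalized AvgIpc carries the same information
_EXCLUDED_DESCRIPTORS = {"Ipc"}
_MAX_MAGNITUDE = 1e30  # anything beyond this is treated as a failed value


def _descriptors_for_mol(mol: Chem.Mol) -> dict[str, float]:
    values = _RD.CalcMolDescriptors(mol)
    for name in _EXCLUDED_DESCRIPTORS:
        values.pop(name, None)
    values["ArBondCount"] = aromatic_bond_count(mol)
    values["Chi6ch"] = chi6_chain(mol)
    return values


def compute_descriptor_matrix(curated: Sequence[CuratedStructure]) -> DescriptorMatrix:
    """Compute the 1D/2D descriptor table for a curated library.

    Failed descriptor values (NaN/inf) are imputed with the column median;
    a column failing on more than 10% of the chemicals is dropped.  The
    returned matrix contains no missing values.
    """
    if len(curated) == 0:
        raise InputError("cannot compute descriptors for an empty library")
    rows = {}
    for entry in curated:
        mol = Chem.MolFromSmiles(entry.smiles_std)
        if mol is None:
            raise InputError(f"chemical {entry.id!r} is not QSAR-ready")
        rows[entry.id] = _descriptors_for_mol(mol)
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df = df.replace([np.inf, -np.inf], np.nan)
    df = df.mask(df.abs() > _MAX_MAGNITUDE)

    failed_fraction = df.isna().mean()
    dropped = failed_fraction[failed_fraction > _MAX_FAILED_FRACTION].index
    df = df.drop(columns=dropped)
    df = df.fillna(df.median())
    df = df.dropna(axis=1, how="all")  # column failing everywhere at small n
    return DescriptorMatrix(values=df, provenance={c: "computed" for c in df.columns})


def merge_external_descriptors(
    matrix: DescriptorMatrix, table: pd.DataFrame
) -> DescriptorMatrix:
    """Append externally predicted descriptor columns (e.g. physicochemical
    property model output) keyed by chemical id.

    Chemicals absent from ``table`` get median imputation; ids in ``table``
    that are not in the matrix, or column-name collisions, are errors.
    """
    if table.empty and len(table.columns) == 0:
        return matrix
    unknown = set(table.index) - set(matrix.ids)
    if unknown:
        raise InputError(f"external table has unknown chemical ids: {sorted(unknown)[:5]}")
    collisions = set(table.columns) & set(matrix.names)
    if collisions:
        raise InputError(f"external descriptor names collide: {sorted(collisions)}")
    external = table.reindex(matrix.ids).astype(float)
    external = external.fillna(external.median())
    merged = pd.concat([matrix.values, external], axis=1)
    provenance = dict(matrix.provenance)
    provenance.update({c: "external" for c in table.columns})
    return DescriptorMatrix(values=merged, provenance=provenance)


def remove_uninformative(
    matrix: DescriptorMatrix, near_constant_fraction: float = 0.90
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Drop zero-variance columns and columns whose modal value covers more
    than ``near_constant_fraction`` of the chemicals (strict inequality)."""
    df = matrix.values
    if len(df) < 2:
        raise InputError("need at least 2 chemicals to assess descriptor variance")
    null_variance = [c for c in df.columns if df[c].nunique() <= 1]
    remaining = df.drop(columns=null_variance)
    if remaining.shape[1] == 0:
        raise PipelineError("all descriptors were dropped as uninformative")
    modal_fraction = remaining.apply(lambda col: col.value_counts().iloc[0] / len(col))
    near_constant = list(modal_fraction[modal_fraction > near_constant_fraction].index)
    kept = remaining.drop(columns=near_constant)
    if kept.shape[1] == 0:
        raise PipelineError("all descriptors were dropped as uninformative")
    report = SelectionReport(
        dropped_null_variance=null_variance,
        dropped_near_constant=near_constant,
        near_constant_fraction=near_constant_fraction,
    )
    provenance = {c: matrix.provenance.get(c, "computed") for c in kept.columns}
    return DescriptorMatrix(values=kept, provenance=provenance), report


def correlation_cluster_select(
    matrix: DescriptorMatrix,
    threshold: float = 0.9,
    seed: int = 0,
    report: SelectionReport | None = None,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Keep one descriptor per correlation cluster.

    Clusters are connected components of the graph whose edges join columns
    with \\|Pearson r\\| > ``threshold``; the representative of each cluster is
    drawn with a seeded RNG.  Absolute correlation is used because
    anti-correlated descriptors are equally redundant.  Note the contract is
    component-based: two retained descriptors from different components can
    in principle correlate above the threshold only through a dropped
    mediator; within a component exactly one column survives.
    """
    df = matrix.values
    corr = df.corr().abs()
    graph = nx.Graph()
    graph.add_nodes_from(df.columns)
    cols = list(df.columns)
    arr = corr.to_numpy()
    rows_i, cols_j = np.where(np.triu(arr, k=1) > threshold)
    graph.add_edges_from((cols[i], cols[j]) for i, j in zip(rows_i, cols_j))

    rng = np.random.default_rng(seed)
    keep: list[str] = []
    clusters: list[dict] = []
    for component in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        members = sorted(component)
        representative = members[int(rng.integers(len(members)))]
        keep.append(representative)
        clusters.append({"members": members, "representative": representative})
    keep = [c for c in df.columns if c in set(keep)]  # preserve column order

    out_report = report if report is not None else SelectionReport()
    out_report.correlation_clusters = clusters
    out_report.threshold = threshold
    out_report.seed = seed
    provenance = {c: matrix.provenance.get(c, "computed") for c in keep}
    return DescriptorMatrix(values=df[keep], provenance=provenance), out_report


def select_descriptors(
    matrix: DescriptorMatrix, threshold: float = 0.9, seed: int = 0
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Run the full two-stage selection (uninformative filter, then
    correlation clustering)."""
    filtered, report = remove_uninformative(matrix)
    return correlation_cluster_select(filtered, threshold=threshold, seed=seed, report=report)


def standardize_matrix(
    matrix: DescriptorMatrix,
    scaler: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Z-score each descriptor column.

    Returns the scaled DataFrame and the scaler parameters (mean, std).
    Pass a previously returned ``scaler`` to apply a training-set scaling to
    new chemicals.
    """
    df = matrix.values
    if scaler is None:
        mean = df.mean()
        std = df.std(ddof=0).replace(0.0, 1.0)
        scaler = {"mean": mean, "std": std}
    scaled = (df - scaler["mean"]) / scaler["std"]
    return scaled, dict(scaler)
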