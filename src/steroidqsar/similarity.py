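"""MACCS fingerprints, Tanimoto similarity, applicability-domain scores and
classical MDS projection of similarity matrices.

Similarity throughout is the Tanimoto coefficient |A∩B| / |A∪B| over the
166-key MACCS substructure fingerprint: 1 means the two fingerprints are
identical, 0 means they share no keys.  The applicability-domain (AD) score
of a query against a training set is its similarity to the nearest training
chemical, so every training member scores 1 against its own training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .curation import CuratedStructure
from .errors import InputError

# Reference hormone structures (2D, stereo as registered).
ESTRADIOL_SMILES = "C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc34)[C@@H]1CC[C@@H]2O"
PROGESTERONE_SMILES = "CC(=O)[C@H]1CC[C@H]2[C@@H]3CCC4=CC(=O)CC[C@]4(C)[C@H]3CC[C@]12C"


@dataclass(frozen=True)
class Fingerprint:
    """Set of on-keys (1..166) of the MACCS vocabulary for one chemical."""

    id: str
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if any(not 1 <= b <= 166 for b in self.bits):
            raise InputError("MACCS key indices must lie in [1, 166]")


def maccs_fingerprint(structure: str | CuratedStructure, id: str = "") -> Fingerprint:
    """MACCS 166-key fingerprint of a curated structure (deterministic)."""
    if isinstance(structure, CuratedStructure):
        if not structure.ok:
            raise InputError(f"structure {structure.id!r} was rejected during curation")
        smiles, id = structure.smiles_std, structure.id
    else:
        smiles = structure
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"cannot parse structure {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)
    return Fingerprint(id=id, bits=frozenset(bv.GetOnBits()) - {0})


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; two empty fingerprints score 0."""
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass
class SimilarityProfile:
    """Per-chemical similarity of a library against one reference."""

    reference_id: str
    scores: dict[str, float]
    mean: float
    sd: float


def similarity_profile(
    fingerprints: Sequence[Fingerprint], reference: Fingerprint
) -> SimilarityProfile:
    """Tanimoto of every library chemical against a reference, with mean ± sd."""
    if len(fingerprints) == 0:
        raise InputError("similarity profile requires a non-empty library")
    scores = {fp.id: tanimoto(fp, reference) for fp in fingerprints}
    values = np.fromiter(scores.values(), dtype=float)
    return SimilarityProfile(
        reference_id=reference.id,
        scores=scores,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
    )


def ad_score(
    query: Fingerprint, training: Iterable[Fingerprint], mode: str = "nearest"
) -> float:
    """Applicability-domain score of a query against a training set.

    ``mode="nearest"`` (default) scores similarity to the closest training
    chemical; ``mode="minimum"`` scores similarity to the farthest one (the
    literal minimum, kept for comparison — it collapses to ~0 on any diverse
    training set).
    """
    scores = [tanimoto(query, t) for t in training]
    if not scores:
        raise InputError("AD score requires a non-empty training set")
    if mode == "nearest":
        return max(scores)
    if mode == "minimum":
        return min(scores)
    raise InputError(f"unknown AD mode {mode!r}; use 'nearest' or 'minimum'")


def pairwise_similarity_matrix(fingerprints: Sequence[Fingerprint]) -> pd.DataFrame:
    """Symmetric Tanimoto matrix with unit diagonal, ids as index/columns."""
    n = len(fingerprints)
    ids = [fp.id for fp in fingerprints]
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def mds_projection(similarity: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a similarity matrix into 2D.

    Distances are 1 − similarity.  The projection is deterministic: the
    double-centered distance matrix is eigendecomposed and the two leading
    coordinates returned, with each axis's sign fixed so its
    largest-magnitude loading is positive.  Distances of any 2D-embeddable
    matrix are reproduced exactly.
    """
    mat = similarity.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise InputError("similarity matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise InputError("similarity matrix must have a unit diagonal")
    dist = 1.0 - mat
    n = dist.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (dist**2) @ centering
    eigenvalues, eigenvectors = np.linalg.eigh(b)
    order = np.argsort(eigenvalues)[::-1][:2]
    coords = np.zeros((n, 2))
    for axis, idx in enumerate(order):
        lam = max(eigenvalues[idx], 0.0)
        vec = eigenvectors[:, idx] * np.sqrt(lam)
        pivot = np.argmax(np.abs(vec))
        if vec[pivot] < 0:
            vec = -vec
        coords[:, axis] = vec
    return pd.DataFrame(coords, index=similarity.index, columns=["x", "y"])
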