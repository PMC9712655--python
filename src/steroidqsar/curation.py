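"""Structure standardization and library curation.

Raw structure strings are turned into QSAR-ready canonical SMILES by:
stripping explicit hydrogens, removing counter-ion / solvent fragments
(largest-organic-fragment rule with a standard allowlist), rejecting
metal-containing or multi-organic-fragment mixtures and unparseable strings,
keeping declared stereochemistry flags while dropping invalid ones, and
canonicalizing the survivor.  Standardization is idempotent: feeding a
curated SMILES back in returns it unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import InputError
from .records import ChemicalRecord, check_unique_ids

RDLogger.DisableLog("rdApp.*")

REJECTION_REASONS = ("none", "mixture", "inorganic_or_metal", "unparseable", "no_structure")

# Elements allowed in an organic QSAR-ready structure; anything else is
# treated as a metal/inorganic component.
_ORGANIC_ELEMENTS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}

# Common counter-ions and solvents (canonical SMILES), stripped when they
# accompany a main organic fragment.
_COUNTERION_SOLVENT = {
    "O",                  # water
    "CO",                 # methanol
    "CCO",                # ethanol
    "CC(C)=O",            # acetone
    "CC(=O)O", "CC(=O)[O-]",      # acetic acid / acetate
    "C(=O)O", "O=CO", "O=C[O-]",  # formic acid / formate
    "OC(=O)C(=O)O", "O=C(O)C(=O)O",  # oxalic acid
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",  # methanesulfonate
    "OS(=O)(=O)O", "O=S(=O)(O)O", "[O-]S(=O)(=O)[O-]", "[O-]S(=O)(=O)O",  # sulfate
    "O=[N+]([O-])O", "[O-][N+](=O)[O-]",  # nitrate
    "OC(=O)C(F)(F)F", "O=C(O)C(F)(F)F",   # trifluoroacetic acid
    "Cl", "[Cl-]", "Br", "[Br-]", "I", "[I-]", "F", "[F-]",
    "[NH4+]", "N",
}

_MIXTURE_MIN_HEAVY = 8  # two organic fragments this large -> mixture


@dataclass
class CuratedStructure:
    """Outcome of standardizing one structure.

    ``smiles_std`` is non-empty exactly when ``rejection_reason == "none"``.
    """

    id: str
    smiles_std: str
    rejection_reason: str = "none"

    @property
    def ok(self) -> bool:
        return self.rejection_reason == "none"


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(atom.GetSymbol() not in _ORGANIC_ELEMENTS for atom in mol.GetAtoms())


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms())


_NEUTRALIZABLE = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    # protonate/deprotonate simple charged centers not balanced internally
    for (idx,) in mol.GetSubstructMatches(_NEUTRALIZABLE):
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h_count - charge)
        atom.UpdatePropertyCache()
    return mol


def _finalize(mol: Chem.Mol) -> str:
    mol = _neutralize(Chem.RWMol(mol))
    mol = Chem.RemoveHs(mol)
    # keep declared stereo flags, drop ones that are no longer meaningful
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return Chem.MolToSmiles(mol)


def standardize_structure(smiles_raw: str, id: str = "") -> CuratedStructure:
    """Standardize one raw SMILES string into QSAR-ready form.

    Returns a :class:`CuratedStructure` whose ``rejection_reason`` is one of
    ``none``, ``mixture``, ``inorganic_or_metal``, ``unparseable`` or
    ``no_structure``.
    """
    if smiles_raw is None:
        return CuratedStructure(id=id, smiles_std="", rejection_reason="no_structure")
    if not isinstance(smiles_raw, str) or not smiles_raw.strip():
        return CuratedStructure(id=id, smiles_std="", rejection_reason="unparseable")

    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return CuratedStructure(id=id, smiles_std="", rejection_reason="unparseable")

    frags = list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))
    if len(frags) == 1:
        if _contains_metal(mol) or not _has_carbon(mol):
            return CuratedStructure(id=id, smiles_std="", rejection_reason="inorganic_or_metal")
        return CuratedStructure(id=id, smiles_std=_finalize(mol))

    # multi-fragment: drop metal-containing and carbon-free fragments, then
    # allowlisted counter-ions/solvents — unless only allowlisted organics
    # remain (e.g. sodium acetate), in which case they are the chemical
    carbon_frags = []
    for frag in frags:
        if _contains_metal(frag) or not _has_carbon(frag):
            continue
        carbon_frags.append((frag, Chem.MolToSmiles(frag)))
    organics = [(f, c) for f, c in carbon_frags if c not in _COUNTERION_SOLVENT]
    if not organics:
        organics = carbon_frags
    if not organics:
        return CuratedStructure(id=id, smiles_std="", rejection_reason="inorganic_or_metal")

    distinct = {canon: frag for frag, canon in organics}
    if len(distinct) > 1:
        big = [f for f in distinct.values() if f.GetNumHeavyAtoms() >= _MIXTURE_MIN_HEAVY]
        if len(big) > 1:
            return CuratedStructure(id=id, smiles_std="", rejection_reason="mixture")
    # largest organic fragment; ties broken by canonical SMILES for determinism
    keep = max(distinct.items(), key=lambda kv: (kv[1].GetNumHeavyAtoms(), kv[0]))[1]
    return CuratedStructure(id=id, smiles_std=_finalize(keep))


def curate_library(
    records: Sequence[ChemicalRecord],
) -> tuple[list[CuratedStructure], dict[str, int]]:
    """Standardize a whole library, preserving input order.

    Returns the non-rejected curated structures and a per-reason rejection
    tally (reasons with zero count are omitted).
    """
    check_unique_ids(records)
    curated: list[CuratedStructure] = []
    tally: Counter[str] = Counter()
    for rec in records:
        result = standardize_structure(rec.smiles_raw, id=rec.id)
        if result.ok:
            curated.append(result)
        else:
            tally[result.rejection_reason] += 1
    return curated, dict(tally)


def read_library_sdf(path) -> list[ChemicalRecord]:
    """Read a library from an SDF file.

    The record id is taken from the ``id`` property, falling back to the
    molecule title, falling back to a positional id; ``casrn``/``name``
    properties are carried through when present.
    """
    records: list[ChemicalRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for position, mol in enumerate(supplier):
        if mol is None:
            records.append(ChemicalRecord(id=f"sdf{position}", smiles_raw=""))
            continue
        props = mol.GetPropsAsDict()
        rec_id = str(props.get("id") or mol.GetProp("_Name") or f"sdf{position}")
        records.append(
            ChemicalRecord(
                id=rec_id,
                smiles_raw=Chem.MolToSmiles(mol),
                casrn=str(props.get("casrn", "")),
                name=str(props.get("name", "")),
            )
        )
    check_unique_ids(records)
    return records


def qsar_pool_accounting(
    total: int, active: int, borderline: int, single_dose_active: int
) -> int:
    """Size of the inactive pool for one endpoint's QSAR model.

    The inactive pool excludes, from the full tested set, the actives and the
    two uncertain-activity groups (borderline actives and chemicals active
    only in the single-dose screen), which are set aside from both classes.
    """
    for name, value in (
        ("total", total),
        ("active", active),
        ("borderline", borderline),
        ("single_dose_active", single_dose_active),
    ):
        if value < 0:
            raise InputError(f"{name} must be non-negative")
    pool = total - active - borderline - single_dose_active
    if pool < 0:
        raise InputError("excluded groups exceed the total set size")
    return pool
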