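"""Standardize raw structures and build the selected descriptor matrix.

Shows salt stripping, desolvation, mixture/metal rejection, and the
two-stage descriptor selection (uninformative filter, then |r| > 0.9
correlation clustering).
"""

from steroidqsar import (
    ChemicalRecord,
    compute_descriptor_matrix,
    curate_library,
    select_descriptors,
    standardize_structure,
)

for raw in ["CC(=O)[O-].[Na+]", "c1ccccc1.CCO", "O=[Ti]=O", "Cl.Nc1ccccc1"]:
    result = standardize_structure(raw)
    outcome = result.smiles_std if result.ok else f"rejected ({result.rejection_reason})"
    print(f"{raw:25s} -> {outcome}")

records = [
    ChemicalRecord(id="aniline_hcl", smiles_raw="Cl.Nc1ccccc1"),
    ChemicalRecord(id="phenol", smiles_raw="Oc1ccccc1"),
    ChemicalRecord(id="atrazine", smiles_raw="CCNc1nc(Cl)nc(NC(C)C)n1"),
    ChemicalRecord(id="malathion", smiles_raw="CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC"),
    ChemicalRecord(id="titania", smiles_raw="O=[Ti]=O"),
]
curated, rejections = curate_library(records)
print(f"\ncurated {len(curated)} of {len(records)}; rejections: {rejections}")

matrix = compute_descriptor_matrix(curated)
selected, report = select_descriptors(matrix, seed=0)
print(f"descriptors computed:  {len(matrix.names)}")
print(f"dropped (null var):    {len(report.dropped_null_variance)}")
print(f"dropped (near const):  {len(report.dropped_near_constant)}")
print(f"retained after |r|>0.9 clustering: {len(selected.names)}")
print(f"aromatic bond count per chemical:\n{matrix.values['ArBondCount'].to_string()}")

# Atrazine's triazine ring and malathion's dithiophosphate survive curation
# untouched; the titanium oxide is rejected as inorganic.
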