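"""Hormone similarity profiling and SOM activity-enrichment maps.

Computes the MACCS/Tanimoto worked example (estradiol vs progesterone),
profiles a synthetic library against estradiol, clusters it with a
self-organizing map and reports the most activity-enriched cluster.
"""

from steroidqsar import (
    ESTRADIOL_SMILES,
    PROGESTERONE_SMILES,
    SyntheticConfig,
    cluster_activity_enrichment,
    cluster_similarity_summary,
    compute_descriptor_matrix,
    curate_library,
    fit_som,
    generate_library,
    maccs_fingerprint,
    scan_grid_sizes,
    select_descriptors,
    similarity_profile,
    standardize_matrix,
    tanimoto,
)

e2 = maccs_fingerprint(ESTRADIOL_SMILES, id="estradiol")
p4 = maccs_fingerprint(PROGESTERONE_SMILES, id="progesterone")
print(f"estradiol vs progesterone Tanimoto: {tanimoto(e2, p4):.3f}  (prints as 0.58)")

library = generate_library(
    SyntheticConfig(n_chemicals=400, motif_effects={"phenol": 8}, seed=3)
)
curated, _ = curate_library(library.records)
fingerprints = [maccs_fingerprint(c) for c in curated]
profile = similarity_profile(fingerprints, e2)
print(f"library similarity to estradiol: {profile.mean:.2f} ± {profile.sd:.2f}")

matrix = compute_descriptor_matrix(curated)
selected, _ = select_descriptors(matrix, seed=0)
scaled, _ = standardize_matrix(selected)

print("\ngrid scan (balance cluster count vs occupancy):")
print(scan_grid_sizes(scaled, [(3, 3), (4, 4), (6, 6)], seed=0).to_string(index=False))

som = fit_som(scaled, grid=(4, 4), seed=0)
assignments = som.assign(scaled)
labels = {r.id: r.labels["E2up"] for r in library.records}
profiles = cluster_activity_enrichment(assignments, {"E2up": labels})
top = profiles["prop_E2up"].idxmax()
print(f"\nmost enriched cluster: #{top} "
      f"({profiles.loc[top, 'prop_E2up']:.0%} active, size {profiles.loc[top, 'size']})")
sims = cluster_similarity_summary(assignments, profile)
print(f"cluster mean estradiol-similarity range: {sims.min():.2f}–{sims.max():.2f}")

# The enriched cluster concentrates phenol carriers: activity enrichment on
# the map flags the structural neighborhood driving the planted signal.
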