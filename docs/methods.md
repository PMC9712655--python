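# Methods

This note documents the models and procedures implemented in `steroidqsar`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Problem setting

A high-throughput steroidogenesis screen labels each chemical in a library
as increasing estradiol (E2up), increasing progesterone (P4up), inactive,
or excluded (borderline/uncertain activity that belongs to neither class).
Roughly 10% of tested chemicals are active for either endpoint.  The
package profiles the structural features associated with activity (SOM
clustering, chemotype enrichment) and predicts activity for new structures
(binary QSAR with an applicability-domain-aware confidence score).

## Structure curation

Raw SMILES are standardized by: parsing; splitting multi-fragment inputs;
removing metal-containing and carbon-free fragments and allowlisted
counter-ions/solvents (water, common alcohols, halide acids, sulfate,
nitrate, ammonium, acetate, oxalate, mesylate, TFA); keeping the largest
remaining organic fragment; neutralizing simple charged centers;
normalizing stereo flags (declared stereo kept, meaningless flags dropped);
removing explicit hydrogens; and canonicalizing.  Decisions the procedure
needs that the bare step names do not fix:

- **Mixture rule** — two *distinct* non-allowlisted organic fragments each
  with ≥ 8 heavy atoms is a mixture and is rejected; a smaller second
  fragment is treated as a salt/solvent and stripped.  Eight heavy atoms
  separates genuine co-formulants from counter-ions in practice.
- **Allowlist scope** — counter-ion/solvent stripping applies only when a
  non-allowlisted organic fragment remains; sodium acetate therefore
  curates to acetic acid rather than vanishing.
- **Idempotence** — `standardize(standardize(s)) == standardize(s)`; this is
  asserted in the test suite and relied on by the synthetic generator,
  whose canonicalized output passes curation unchanged.

Rejection reasons are `mixture`, `inorganic_or_metal`, `unparseable`,
`no_structure`; libraries report a per-reason tally.

## Descriptors and selection

The descriptor block is the RDKit 2D set (~210 columns: constitutional
counts, topological and chi/kappa connectivity indices, E-state sums, BCUT
Burden eigenvalues, information indices, MOE-type VSA descriptors, QED
drug-likeness) plus two named composition indices: `ArBondCount` (aromatic
bond count; benzene = 6) and `Chi6ch`, a simple connectivity index over
six-membered rings (Π 1/√δ over ring atoms, summed over 6-rings; benzene =
0.125).  Raw `Ipc` is excluded: it grows super-exponentially with molecule
size and overflows 32-bit floats downstream; the size-normalized `AvgIpc`
carries the same information.  Failed values (NaN/±inf or magnitude >
1e30) are imputed with the column median; a column failing on more than 10%
of chemicals is dropped.  The matrix is guaranteed complete after
computation.

Selection is two-stage:

1. **Uninformative filter** — drop zero-variance columns and columns whose
   modal value covers strictly more than 90% of chemicals (a column at
   exactly 90% survives).
2. **Correlation clustering** — connected components of the graph joining
   columns with |Pearson r| > 0.9; one seeded-random representative per
   component is kept.  Absolute correlation is used because anti-correlated
   descriptors are equally redundant; components are the weakest clustering
   assumption consistent with "clustered by pairwise correlation".  The
   retained-set contract is component-based: two survivors from different
   components can in principle correlate above 0.9 only through a dropped
   mediator.

Selection is deterministic given its seed and idempotent (re-running on the
selected matrix is the identity).  Z-scoring (population σ) is applied
before SOM training and any scale-sensitive learner; forests consume raw
values.

## Similarity and applicability domain

Fingerprints are the 166-key MACCS set; similarity is Tanimoto
|A∩B|/|A∪B|, with the empty-vs-empty case defined as 0 (conservative
dissimilarity).  Estradiol and progesterone share 23 of 40 on-keys —
0.575, printed as 0.58 at the customary two decimals (half-up rounding).

The applicability-domain score of a query is its Tanimoto similarity to the
**nearest** training chemical, so training members score exactly 1 and the
0.75 high-confidence cut is meaningful.  A literal minimum over a diverse
training set is ≈ 0 for every query and carries no information; it remains
available as `mode="minimum"` for comparison.

Similarity matrices are projected to 2D by classical (Torgerson) MDS on
distances 1 − s: double-center, eigendecompose, keep the two leading
coordinates, and fix each axis sign so its largest-magnitude loading is
positive — fully deterministic, and exact for any 2D-embeddable matrix.

## Self-organizing map

Rectangular, non-toroidal grid of codebook vectors trained online:
random-sample presentations with the best-matching unit pulled toward the
sample under a Gaussian grid-neighborhood.  Learning rate decays linearly
0.5 → 0.01 and radius max(rows, cols)/2 → 0.5 over 10·n presentation
steps; the codebook is initialized from jittered data samples.  Training is
deterministic given the seed.  Grid size is a scientific choice, not a
fitted parameter: `scan_grid_sizes` reports empty-cluster counts and
min/median/max occupancy per candidate grid so the user can balance cluster
count against occupancy (an 8×8 grid = 64 clusters is the usual operating
point at n ≈ 2000).  Empty clusters are allowed and reported as missing
proportions.  Per-cluster activity enrichment is the active proportion
among labeled members (excluded labels count toward size but not
proportions); the occupancy-weighted mean of proportions equals the global
active fraction exactly.

Because SOM training schedules are not identifiable from cluster profiles,
enrichment conclusions should be checked across seeds rather than matched
cluster-for-cluster; the suite asserts cross-seed recovery of planted
enrichment, not specific cluster geometry.

## Chemotype enrichment

A chemotype matrix is binary chemicals × features, either loaded from a
batch-search export (TSV/CSV, first column ids, strict 0/1 validation) or
matched with the built-in SMARTS vocabulary (benzene, phenol, aromatic and
primary/secondary amines, benzidine-type diamine, 1,3,5-triazine ring, aryl
halide, thio/dithiophosphate, phenyl-alkane, naphthalene, sulfonyl).

Each chemotype is tested on the 2×2 table (active vs non-active) × (has vs
lacks) with Pearson's chi-squared, two-sided, without continuity
correction; the background is the full tested set including the actives.
Two-sided matters: depletion (e.g. a sulfonyl group underrepresented among
actives) is a finding too.  Rows are ordered by ascending p; tiers are
*** p < 0.001, ** p < 0.01, * p < 0.05; a `reported` flag marks chemotypes
present in > 20% of actives; rows with any expected count < 5 are flagged
`low_expected_count`; chemotypes absent (or ubiquitous) are `untestable`.
Raw p-values drive the tiers, matching common practice for structural-alert
profiling; a Benjamini–Hochberg column is emitted alongside for
transparency.

The co-occurrence network takes chemotypes with p < 0.01 as nodes
(annotated with active counts) and weights each edge by the number of
active chemicals containing both chemotypes; zero-weight edges are omitted,
so an edge weight never exceeds either endpoint's count.

## QSAR modeling

**Learners.**  Plain random forest (scikit-learn, 200 trees, OOB scoring
enabled) and a balanced random forest in which each of 200 unpruned trees
is grown on a bootstrap of n_minority draws *per class*, holding every
tree's prior at 50:50; probabilities average over trees.  Any
probability-emitting scikit-learn-style estimator can be plugged in
instead.  Model selection is a grid search scored by mean MCC over
stratified 10-fold cross-validation, refit on the full training set; the
default grid is a single sensible point (unpruned, √p features), since
forest performance is flat over reasonable grids at these sample sizes.

**Splits.**  Repeated stratified train/test splits (default 15% test, 5
repeats, seeded); stratification guarantees both classes in every split at
10% prevalence.  When all repeats are run, the pipeline reports every
repeat rather than silently keeping the best one — selecting the maximum
is an optimistic-bias choice that should at least be visible.

**GHOST threshold shifting.**  Candidate cutoffs 0.05–0.50 (step 0.05) are
scored on 50 stratified 80% subsamples of the training set; the cutoff
with the best median score wins, ties resolved toward 0.5.  The tuning
metric is MCC (consistent with model selection; Cohen's kappa is available
by flag).  The scan uses **out-of-bag** probabilities whenever the
estimator provides them: fully grown forests memorize their training
chemicals, which saturates resubstitution probabilities and makes every
low cutoff tie — the OOB curve is the honest generalization proxy.  The
threshold shift is applied uniformly to both forests.

**Metrics.**  SE, SP, Acc, bAcc = (SE+SP)/2, MCC, plus rank-based
(Mann–Whitney) AUC with half-credit ties.  Conventions for degenerate
counts: SE or SP with a zero denominator is reported missing (NaN); an MCC
with a zero denominator is 0, so an all-inactive predictor scores
SE 0 / SP 1 / bAcc 0.5 / MCC 0.  Cross-validation reports per-fold metrics
and pooled metrics from summed confusion counts (pooled AUC from
concatenated out-of-fold probabilities); leave-one-out falls back from
stratified to plain folds.

**Confidence-tiered prediction.**  Each query gets: active probability;
label at the model's (shifted) threshold; AD score against the training
fingerprints; and the count of present chemotypes that are significant
(p < 0.05) in the training enrichment.  Predicted actives are tiered
**high** when all three criteria hold (probability > 0.5, AD ≥ 0.75, more
than three significant chemotypes), **medium** on exactly two, **low**
otherwise; the tier is not applicable to predicted inactives.  The
two-of-three/medium rule is this package's resolution of the tier
boundaries, which are otherwise underdetermined.

## Synthetic-data generator

The generator exists so every stage is testable without external data.  It
emulates: (i) a majority-inactive background of small drug-like /
pesticide-like molecules at a configurable base active rate (default 0.10,
the screening regime's prevalence); (ii) enrichment of specific
substructure families among actives — amino-triazine, phenol, aromatic
primary amine, benzidine-type diamine, phosphorodithioate ester, aryl
halide — the motif families that steroidogenesis-screen profiling flags.

Structures are assembled by template substitution over a curated grammar:
an alkyl backbone carries one background scaffold (butyl/isopentyl chain,
cyclohexane, benzene, pyridine), each planted motif fragment in its own
branch, and 0–2 benign substituents; ring-closure digits are assigned
per molecule, so every SMILES is valid by construction, single-fragment,
salt-free and metal-free, and is emitted canonicalized (hence curation is
the identity on generated libraries).  Motif templates are chosen to be
mutually orthogonal with respect to each motif's defining chemotype (the
triazine template carries methoxy/thioether handles, not amines or
halides), except for the unavoidable chemical fact that a benzidine-type
diamine contains aromatic primary amines.

Activity is logistic per motif *instance*: log-odds = logit(active_rate) +
Σ copies·ln(OR), with copies = 1 + Binomial(k, 0.5) per planted motif
(k = `motif_extra_copies`, default 3; k = 0 gives the strict set-based
model), then an optional symmetric label flip with probability
`label_noise`.  Instance-additivity is deliberate: real actives often carry
repeated halide or hydroxyl substitutions (trichlorophenols,
polyphenols), and a strictly binary one-copy effect at OR = 8 from a 10%
base caps the Bayes-optimal balanced accuracy near 0.74, too little
headroom to distinguish a working pipeline from a broken one.  Defaults
chosen once: per-motif planting prevalence 0.25 (common-substructure
territory for pesticide-like libraries), default `motif_effects = {}` so
the default library's active fraction equals the base rate exactly.

What the generator does **not** emulate: synthesis feasibility, 3D
conformers/stereochemistry-dependent activity, the long-tailed size and
scaffold diversity of real inventories, correlated motif planting, or
assay-specific noise structure.  Passing tests on generated libraries
demonstrate that the pipeline recovers planted signal under realistic
prevalence and noise — not that any real chemical class is or is not
steroidogenic.

## Problem sizes used in validation

The self-checks run at the scale the statistics need and no more:
enrichment recovery at n = 2000 across 20 seeds (planted odds ratio 8,
no label noise); parameter recovery at n = 2000 across 5 seeds (base rate
0.10, one OR = 8 motif, 5% label noise), where the balanced forest's
median external bAcc and its sensitivity margin over the plain forest are
asserted; the GHOST scan behavior on an ~11%-prevalence single-instance
library (n = 1500), where the shifted cutoff falls below 0.5; and the
metric-formula oracle on 1,000 random confusion tables at 1e-12.

## Known limitations

- The built-in chemotype vocabulary is a dozen features, not a full
  toxicological fingerprint; external chemotype matrices cover that need.
- Chi-squared p-values are asymptotic; rows with expected counts < 5 are
  flagged rather than switched to an exact test.
- The SOM is an online implementation without batch training or toroidal
  topology; cluster identities are seed-dependent by nature.
- The balanced forest's probability scale is calibrated to a 50:50 prior,
  not the population prevalence; thresholds tuned by GHOST absorb this,
  but raw probabilities should not be read as population risks.
- Descriptor provenance distinguishes computed from externally merged
  columns, but externally predicted physicochemical properties are taken
  at face value.
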