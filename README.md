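# steroidqsar

Cheminformatics profiling and QSAR classification of chemicals that
increase estradiol (E2) or progesterone (P4) synthesis.

Chemicals that push up E2 or P4 production are a breast-cancer hazard
concern, and high-throughput steroidogenesis screens (H295R adrenocortical
cells) label thousands of structures as E2up/P4up actives or inactives at
roughly 10% active prevalence.  `steroidqsar` implements the full analysis
such a screen feeds, for computational toxicologists and cheminformaticians:

- **curation** — SMILES standardization: salt/solvent stripping by the
  largest-organic-fragment rule, metal/mixture/unparseable rejection,
  charge neutralization, canonicalization (idempotent);
- **descriptors** — ~210 1D/2D RDKit descriptors plus named composition
  indices (`ArBondCount`, `Chi6ch`), then two-stage selection: drop
  zero-variance and >90%-constant columns, then keep one representative per
  connected component of the |Pearson r| > 0.9 correlation graph;
- **similarity** — 166-key MACCS fingerprints with Tanimoto scoring
  T(A,B) = |A∩B| / |A∪B|, reference-hormone similarity profiles,
  nearest-neighbor applicability-domain (AD) scores, and classical MDS
  projection of similarity matrices;
- **som** — self-organizing-map clustering of the standardized descriptor
  matrix with grid-size scanning and per-cluster activity-enrichment /
  similarity summaries;
- **chemotypes** — binary chemotype matrices (external batch export or
  built-in SMARTS vocabulary), per-chemotype Pearson chi-squared enrichment
  of actives vs the full tested set with */**/*** tiers, and co-occurrence
  networks of significant chemotypes;
- **qsar** — random forest and balanced random forest (per-tree
  class-balanced bootstrap) behind a pluggable learner interface, grid
  search by 10-fold cross-validated MCC, GHOST decision-threshold shifting
  on out-of-bag probabilities, the SE/SP/Acc/bAcc/MCC/AUC metric suite, and
  confidence-tiered prediction (probability, AD score, significant-chemotype
  count);
- **synthetic** — a seeded generator of valid-by-construction chemical
  libraries with planted substructure–activity signal, so the entire
  pipeline is testable end to end without any download.

The core statistics, in the field's usual notation: SE = TP/(TP+FN),
SP = TN/(TN+FP), Acc = (TP+TN)/N, bAcc = (SE+SP)/2, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Under ~10:90 class
imbalance, a learner can score Acc ≈ 0.9 by predicting everything inactive
(SE = 0, MCC = 0); the balanced random forest and the GHOST threshold shift
exist to avoid exactly that failure mode.

## Worked example

`examples/` contains one narrative script per capability.  The QSAR
experiment (`examples/05_qsar_train_and_predict.py`) generates an 800-
chemical library with a planted triazine effect (odds ratio 8 per copy, 5%
label noise), trains a balanced random forest with GHOST threshold
shifting, and validates on a held-out 15%:

```
external validation (held-out 15%):
  SE=0.63 SP=0.89 Acc=0.81 bAcc=0.76 MCC=0.54 AUC=0.80
  decision threshold after GHOST: 0.5
```

SE is the fraction of true actives recovered, SP the fraction of inactives
correctly cleared; bAcc averages them so the 10:90 imbalance cannot hide a
blind classifier.  The script then predicts held-out chemicals as if they
were new queries, reporting for each the active probability, AD score
(similarity to the nearest training chemical), the number of significant
chemotypes present, and the resulting confidence tier — e.g. a strongly
predicted active inside the domain:

```
          probability predicted_label  ad_score  significant_chemotype_count confidence true_label
SYN00311        0.995          active     0.982                            1     medium     active
```

The similarity worked example
(`examples/03_similarity_and_som.py`) reproduces the canonical
hormone-pair similarity: estradiol and progesterone share a MACCS/Tanimoto
score of 0.575 (23 shared keys of 40), printed as 0.58 at two decimals —
their sterol skeleton drives the overlap.

## Layout

```
src/steroidqsar/    library (curation, descriptors, similarity, som,
                    chemotypes, qsar, synthetic, pipeline)
examples/           one narrative script per capability
tests/              pytest suite incl. the acceptance checks
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
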