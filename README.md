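# coopnet

Classifying protein triplets as **cooperative** or **competitive** in a
hyperbolically embedded interaction network.

When a common interactor protein binds two partners (V1 and V2) that do not
bind each other — an *open triangle* — the two partners either occupy
distinct interfaces and can bind simultaneously (cooperative) or compete
for an overlapping interface (competitive). Distinguishing the two from
network context matters to anyone studying complex assembly, signaling
regulation or interface-targeted drug design, because high-throughput
interaction data is pairwise and says nothing about simultaneity.

`coopnet` implements the full inference pipeline:

1. **Network construction** — confidence-scored edge lists (threshold
   ≥ 0.71), self-interaction removal, largest connected component, and the
   four node centralities (degree, closeness, betweenness, eigenvector).
2. **Hyperbolic embedding** — the popularity–similarity (PS) model in the
   native disk, distances via
   `d = arccosh(cosh r₁ cosh r₂ − sinh r₁ sinh r₂ cos Δθ)`, Fermi–Dirac
   edge probability `p(x) = 1/(1 + e^{(x−R)/2T})`, spectral (Laplacian
   eigenmaps) angle initialisation with degree-rank radii
   `r_i = 2β ln i + 2(1−β) ln N`, and per-node maximum-likelihood angular
   refinement.
3. **Triplet mining** — streaming enumeration of all open triangles, with
   the closed-form count `Σ_v C(deg v, 2) − 3·#triangles` as an oracle.
4. **Structural labeling** — cooperative positives from complex tables by
   the exactly-two-of-three contact rule, mapped onto the network's open
   triangles, one triplet per common interactor.
5. **Feature extraction** — 42 features per triplet: 11 per protein
   (coordinates, centralities, disorder flag, localization indicators) × 3
   roles, plus hyperbolic distance / radial difference / angular difference
   for the three pairs; 50% V1/V2 order randomization.
6. **Classification** — stratified 70/30 split, majority undersampling,
   5-fold × 10 cross-validation, Random Forest (500 trees, 22 variables per
   split) against SVM / logistic regression / decision tree / kNN
   benchmarks; accuracy, F1, sensitivity, specificity, ROC/AUC, and
   permutation importance (mean decrease in accuracy).
7. **Interpretation** — degree ≤ 10 filtering, score quartiles
   (Q1 competitive-like … Q4 cooperative-like), paralog-fraction and
   angular-separation trends, score-distribution comparisons.

A first-class **synthetic-data module** generates every input with known
ground truth — PS networks with planted coordinates, complex tables that
induce known cooperative triplets, annotation/paralog tables, and a
planted-signal triplet dataset in which cooperative triplets have
systematically smaller V1–V2 angular separation — so the whole pipeline is
testable offline. See `docs/methods.md` for the model details and design
choices.

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end on a
synthetic study (1000 proteins, γ = 2.97, T = 0.83, seed 7):

```sh
python analysis/01_generate_network.py   # PS network + complexes + annotations
python analysis/02_embed_network.py      # LaBNE+HM embedding + centralities
python analysis/03_mine_label_triplets.py
python analysis/04_train_classifier.py
python analysis/05_interpret_scores.py
```

Selected output:

```
network: 1000 proteins, 1997 interactions
cooperative truth triplets (pre-dedup): 211
angular recovery vs planted truth: 0.711 (spectral) -> 0.701 (refined)
open triangles: 12933 (closed-form count matches enumeration)
structural triplets: 213 exactly-two trios, 211 map to network open
  triangles, 86 after one-per-common dedup
training: 122 balanced rows after undersampling, 625 test rows
cross-validation AUC: 0.710 +/- 0.090 over 50 fits
random_forest        acc 0.678  F1 0.137  AUC 0.707
scored 12933 triplets: 4544 with score >= 0.5, 109 >= 0.9
  all_predictions: n=12933  median score 0.380
  cooperative_labels: n=86  median score 0.796
```

Reading this: the embedder recovers ~0.71 of the planted angular structure
(pairwise circular correlation) from topology alone at the noisy study
temperature; the exactly-two labeler finds 213 structural trios of which
211 are open triangles of the network, deduplicating to 86 positives (one
per common interactor); and the forest trained on those noisy structural
labels ranks held-out positives far above the background (median score
0.80 vs 0.38). The planted-signal dataset — where the angular separation
cleanly separates the classes — is the sharper benchmark: there the forest
reaches held-out AUC ≥ 0.99 with the V1–V2 angular difference as the
top-ranked feature (see `tests/test_acceptance.py`).

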