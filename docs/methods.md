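# Methods

## Problem

In a protein–protein interaction network, an *open triangle* is a trio in
which a central common interactor binds two partners (V1 and V2) that do not
bind each other. Such a trio is *cooperative* when the two partners occupy
distinct interfaces on the common protein and can bind simultaneously, and
*competitive* when their interfaces overlap and binding is mutually
exclusive. `coopnet` implements a pipeline that labels a small positive set
of cooperative triplets from structural complex data, encodes every open
triangle as a 42-dimensional feature vector dominated by hyperbolic-geometry
quantities, and trains a Random Forest to score the remaining triplets.
Everything is exercisable on synthetic data whose generators plant the
statistical structure the method assumes, so the pipeline's behaviour can be
verified against known ground truth without any database downloads.

## Network construction

Scored edge lists (HIPPIE-style TSV: two protein identifiers plus a
confidence in [0, 1]) are thresholded at confidence ≥ 0.71 (inclusive),
self-interactions are dropped, duplicate rows collapse to one undirected
edge (conflicting scores resolve to the maximum), and only the largest
connected component is kept — ties between equal components break on the
lexicographically smallest member, for determinism. Four node centralities
feed the feature matrix: raw integer degree (DC — the downstream low-degree
filter reads naturally on raw degree), closeness (n−1 over summed
distances), pair-normalised betweenness, and the principal adjacency
eigenvector scaled to maximum 1 (EC). Closeness is undefined across
components, so centralities require the post-LCC network.

## Hyperbolic geometry and the PS model

Nodes live in the native hyperbolic disk with polar coordinates (r, θ):
radius encodes popularity (hubs near the centre), angle encodes similarity.
Distances use the exact hyperbolic law of cosines

    d = arccosh(cosh r₁ cosh r₂ − sinh r₁ sinh r₂ cos Δθ),

with the arccosh argument clamped at 1 and the Δθ = 0 limit computed as
|r₁ − r₂| exactly; the common approximation r₁ + r₂ + 2 ln(Δθ/2) is not used
because it breaks down at small separations. Edge likelihoods follow the
Fermi–Dirac form p(x) = 1/(1 + exp((x − R)/(2T))) with cutoff R and
temperature T; T = 0 is the step-function limit.

The popularity–similarity (PS) generator grows a network node by node:
node t appears at a uniform angle with birth radius 2 ln t, earlier nodes
fade outward to 2β ln s + 2(1−β) ln t with β = 1/(γ−1), and the newcomer
links to min(m, t−1) existing nodes — hyperbolically nearest at T = 0,
otherwise sampled without replacement with Fermi–Dirac weights at cutoff
R_t = r_t. Defaults follow the study conditions: γ = 2.97, T = 0.83, full
angular circle. The attachment count m is not dictated by those conditions;
m = 2 is the default (mean degree ≈ 4, a sparse interactome-like regime)
and m = 3 is used where a heavier degree tail helps exponent estimation.
The edge count is exactly Σ_t min(m, t−1) for every seed, which the tests
exploit as a closed-form oracle.

## Embedding (spectral initialisation + likelihood refinement)

Embedding is two-stage, in the LaBNE + HM tradition. The spectral stage
takes the two leading non-trivial generalized eigenvectors of the graph
Laplacian (computed as D^{-1/2}-rescaled eigenvectors of the symmetric
normalized Laplacian, with per-vector sign fixed on the smallest node
identifier so results are backend-independent) and reads each node's angle
as the atan2 of its coordinates in that plane. Radii come from degree rank
under the PS fading rule, r_i = 2β ln i + 2(1−β) ln N. The refinement stage
visits nodes in descending-degree order and replaces each node's angle by
the best of 64 candidates evenly spaced within ±π/6 of the incumbent
(incumbent always included, so the total Bernoulli log-likelihood never
decreases), scored against all other nodes under the Fermi–Dirac model with
R set to the outermost radius. An optional partner cap (neighbours plus
sampled non-neighbours) exists for large graphs; at desk scale the exact
likelihood is used.

Recovery of planted angles is measured by the pairwise Fisher–Lee circular
correlation (absolute value): it is exactly rotation-invariant and flips
sign under reflection, whereas circular-mean-centred variants are unstable
when the angle marginal is near-uniform — during development a
well-recovered embedding (0.21 rad mean aligned error) scored 0.10 under
the mean-centred form and 0.96 under the pairwise form. At N = 300, T = 0.1
the spectral stage alone recovers ≈ 0.88 mean correlation over 10 seeds and
refinement nudges it up slightly (≈ +0.001); refinement's margin is small
because the spectral solution already sits near the static-likelihood
optimum. At T = 0.83 the geometric signal in a 300-node network is largely
washed out (≈ 0.32); recovery checks therefore run at low temperature,
while edge-count and exponent checks run at the study temperature.

The degree exponent is estimated by the continuous maximum-likelihood
formula γ̂ = 1 + n/Σ ln(k_i/(k_min − 0.5)) over nodes with degree ≥ k_min
(default 5); the half-integer offset corrects for integer degrees. On PS
networks of 5000 nodes with γ = 2.97 the estimate lands near 2.81 —
within the ±0.35 band expected for finite-size PS growth.

## Triplet mining and structural labeling

Open triangles are enumerated per common node as neighbour pairs that are
themselves non-adjacent; a streaming iterator avoids materialising the
universe (tens of millions at interactome scale). The closed form
Σ_v C(deg v, 2) − 3·#triangles serves as an independent count oracle.

Structural complex tables (Interactome3D-style TSV: complex id, two
proteins, evidence) are grouped by complex; model-based rows and self-pairs
are dropped and only complexes with ≥ 3 distinct members kept. Within a
complex, every member trio with *exactly two* of its three possible pairwise
contacts is a cooperative triplet whose common interactor is the protein in
both contacts. These are then mapped onto the network: kept only if both
common–partner pairs are network edges and the partner pair is not (trios
closed in the network have no unique centre and are discarded). Finally one
triplet per common interactor survives, first occurrence in dataset order —
row order of the input file, trios visited lexicographically within a
complex — so that structurally rich assemblies (ribosome-like complexes)
cannot flood the positive class.

The synthetic complex generator samples connected node subsets, reports
each within-complex network edge as an observed contact with probability
0.8 (producing exactly-two, all-three and one-contact trios), and computes
its truth list by an independent brute-force trio scan. The labeling
pipeline recovers that truth exactly, pre-deduplication.

## Feature encoding

Each triplet maps to 42 features: 11 per protein role (r, θ, DC, CC, BC,
EC, an intrinsic-disorder flag, and four localization indicators — nucleus,
cytoplasm, endomembrane, multi-localized; an unannotated protein has all
four at 0) for common, V1, V2 (33 node-level values), plus hyperbolic
distance, radial difference and angular difference for each of the three
pairs common–V1, common–V2, V1–V2 (9 edge-level values). The V1–V2 pair is
featurised even though no edge exists there. Proteins missing from the
disorder or localization inputs impute to 0 — zero-imputation keeps the
matrix dense and auditable. Column order is fixed (common block, v1 block,
v2 block, then the three pair blocks) so persisted models can verify their
schema.

To remove positional bias from the canonical v1 < v2 storage order, exactly
⌊n/2⌋ rows (seed-chosen) have V1 and V2 swapped — identities, node blocks
and the common–V1/common–V2 pair blocks exchange; the symmetric V1–V2 block
and labels are untouched. The exact-half convention (rather than
Bernoulli(½) per row) makes the operation a seeded involution, which the
tests verify.

## Classification protocol

Stratified 70/30 split with the train side rounded up per class
(⌈0.7·211⌉ = 148 positives in training), then the majority class is
undersampled without replacement to the minority count — applied once to
the training partition, before cross-validation, giving the 296-row
balanced set the arithmetic implies. Model assessment uses stratified
5-fold cross-validation repeated 10 times (50 fits) with AUC as the
selection metric. The primary model is a Random Forest with 500 trees and
22 variables per split (clamped to the feature count with a warning on
narrower matrices); benchmarks are SVM, logistic regression, decision tree
and kNN, with z-scored features (scaler fit on training data only) for the
distance/margin-based models and raw features for the trees. Scores are
the fitted model's cooperative-class probability (fraction of trees, for
the forest).

Evaluation reports the confusion matrix at threshold 0.5 (configurable)
with accuracy, sensitivity, specificity, precision and F1, plus a full ROC
sweep with trapezoidal AUC; the tests cross-check the AUC against the
Mann–Whitney rank statistic to 1e-9. Feature importance is permutation
based — mean decrease in accuracy over repeated shuffles of one column,
evaluated on held-out rows (on training rows a forest memorises even pure
noise); a constant column scores exactly 0. Genome-wide scoring streams
the feature matrix in chunks with schema validation and bounded memory.

## Interpretation

Scored triplets whose three proteins all have degree ≤ 10 (inclusive) are
cut into four rank-based quartiles — ties broken by stable rank on the
triplet key, bin sizes differing by at most one with the remainder assigned
to the lowest bins first (Q1 gets the largest share). Per quartile the
pipeline reports the fraction of triplets whose {V1, V2} is a paralog pair
(the join is symmetric on the unordered pair; the common protein's paralogy
is ignored) and summary statistics of the V1–V2 angular separation.
Score-distribution summaries (20 fixed-width bins over [0, 1] plus
five-number summaries) support comparing the all-predictions set, the
labeled positives, an external label-disjoint validation set (overlap
removed by exact triplet-key match) and the low-degree subset. Quartiles
are computed on the low-degree subset's own scores.

## Synthetic study design

The planted-signal dataset makes the expected dominant feature explicit:
open triangles below the 0.25 quantile of V1–V2 angular separation form the
cooperative pool, those above it the competitive pool, and disjoint samples
of each are labeled. A classifier that works must find the angular signal;
on this dataset the forest reaches held-out AUC ≥ 0.85, ranks the V1–V2
angular difference first by permutation importance, and produces quartile
trends (median Δθ falling from Q1 to Q4) matching the planted construction,
while label-permuted nulls stay at chance. Paralog pairs are sampled with
weight exp(−Δθ/0.3) from the triplet universe's V1–V2 pairs (genome-wide
random pairs would essentially never coincide with a triplet's partner pair
at desk scale), so the paralog-fraction trend is likewise recoverable.

What the generators deliberately do not emulate: realistic degree-sequence
replication of any specific interactome release, protein sequences or
structures, residue-level interfaces, database identifier formats, or
correlated annotation noise. Passing tests therefore demonstrate that the
pipeline's machinery is correct and recovers planted signal under the
model's own assumptions — not that those assumptions hold for any
particular real dataset.

## Problem sizes and numerical choices

Default study sizes keep every stage exact and fast: networks of 300–1000
nodes for embedding and classification runs, 5000 for exponent estimation,
planted datasets of 1000 triplets, 100-graph batches for combinatorial
oracles. Degenerate inputs are handled explicitly: empty networks and
single-class splits raise, all-equal scores still produce balanced
quartiles, a constant degree tail triggers a degeneracy warning in γ̂,
connection probability clips its exponent against overflow, and likelihood
terms clamp probabilities to (1e-12, 1 − 1e-12). All randomness flows
through seeded `numpy` generators; every generator is bit-reproducible
given (parameters, seed).

## Known limitations

- The refinement stage optimises a static Fermi–Dirac likelihood whose
  cutoff (R = outermost radius) only approximates the grown network's
  time-dependent geometry; its recovery gain over the spectral
  initialisation is accordingly small, and on individual seeds it can be
  marginally negative.
- The noisy-negative convention (unlabeled open triangles treated as
  competitive) imports the usual PU-learning bias; the synthetic bundles
  quantify it only indirectly.
- Localization is a single categorical per protein; real annotation is
  multi-label and the multi-localized category is a coarse stand-in.
- At interactome scale (~17M triplets) the streaming paths are the only
  supported route; the set-returning enumerator and dense feature matrix
  are desk-scale conveniences.
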