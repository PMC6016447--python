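# Methods

`gelscreen` implements a complete QSPR (quantitative structure–property
relationship) workflow for binary gelation prediction in the functionalised
amino-acid / dipeptide family of low-molecular-weight gelators (LMWGs):
molecules of the form *cap–AA* or *cap–AA–AA*, an aromatic or long-alkyl
N-cap amide-bonded to one or two amino-acid residues with a free C-terminal
acid. The endpoint is binary — does a self-supporting hydrogel form after a
slow pH drop — and the workflow runs: featurize → modelability gate → panel
training with repeated-CV selection → statistical quality gates →
y-randomization → applicability-domain fit → combinatorial enumeration →
consensus screen.

## Featurization

Each molecule is canonicalized (RDKit) and encoded as

* **12 physicochemical descriptors**, all computable from the 2D graph (no
  conformers): Crippen AlogP; ESOL-predicted log10 aqueous solubility
  (Delaney's regression on clogP, molecular weight, rotatable bonds and
  aromatic proportion); topological polar surface area (Å²); Labute
  approximate solvent-accessible surface area (Å²); ring count; aromatic
  ring count; rotatable-bond count; molecular weight (g/mol); H-bond donor
  and acceptor counts; heavy-atom count; formal charge. The first six cover
  the descriptor classes known to drive gelation propensity in this family
  (hydrophobicity, solubility, polarity, surface area, rigidity); the rest
  are standard 0D/1D counts.
* **Circular fingerprints**: Morgan radius 2 folded to 1024 bits, binary.

Physchem columns are z-scored with mean/SD frozen on the training rows; the
scaler is never updated by a transform, so test and library rows cannot leak
into it. Fingerprint bits pass through unscaled.

## Modelability (MODI)

Before any modelling, MODI = (1/2) Σ_classes (fraction of class members
whose single nearest neighbour — Euclidean distance in the z-scored
12-descriptor space, self excluded, ties to the lowest row index — shares
their label). MODI > 0.65 is the gate for "amenable to classification".
MODI is computed in descriptor space only (not fingerprint space); the
implementation is vectorised and is cross-checked in the tests against an
O(n²) brute-force recount. A class with fewer than two members makes the
nearest same-class neighbour undefined and is an error.

## Model panel and selection

Seven families share the feature block: RBF-kernel SVM, random forest,
k-nearest neighbours, one-hidden-layer neural network (lbfgs), PLS
discriminant analysis (continuous PLS prediction clipped to [0,1] as
P(gelator)), a mixed naive Bayes (Gaussian likelihood on the scaled
physchem block, Bernoulli on the fingerprint bits, log-likelihoods summed
with the class prior counted once), and a gradient-boosted decision tree.
Small default grids per family (SVM C ∈ {0.1,1,10,100} × γ ∈ {scale, 1e-3,
1e-2}; RF max_features ∈ {sqrt, 0.1}; kNN k ∈ {3,5,7,9}; NN size ∈ {8,16} ×
α ∈ {1e-3,1e-1}; PLS components ∈ {2,3,5,8}; NB α ∈ {0.5,1}; boosted depth
∈ {1,3}) are scanned under **repeated stratified 5-fold CV** (default 10
repeats; the shipped demo and test configurations use 2–3 repeats to keep
wall-time low — the statistic is the same, only its Monte-Carlo error
grows). The winning grid point maximises the mean held-out **H measure**;
ties go to the earlier grid point. The winner is refit on all training rows.
Every split and estimator is seeded, so reruns are bit-identical.

## Evaluation statistics

Positive class = gelator throughout.

* **Cohen's kappa** = (pₒ − pₑ)/(1 − pₑ) with the usual marginal chance
  agreement; on a class-balanced set this reduces exactly to 2·accuracy − 1.
* **Balanced accuracy** = (sensitivity + specificity)/2.
* **Hand's H measure.** For cost c ∈ (0,1) (severity of misclassifying a
  non-gelator; 1−c for a gelator), the minimum expected loss over score
  thresholds is attained on the upper convex hull of the ROC. H = 1 −
  E_c[min loss]/E_c[trivial loss], the expectation over c ~ Beta(2,2) by
  default (configurable). We integrate in closed form via incomplete-Beta
  increments between the hull's cost-indifference breakpoints; the tests
  verify agreement with dense numerical quadrature to 1e-6. Under this
  definition an ideal ranker scores 1 and an uninformative ranker ≈ 0.
  (Some informal accounts put a "random model" at 0.5; that does not follow
  from the definition, and we implement the definition.) Constant scores
  return 0 with a warning.
* **NIR binomial test**: exact one-sided tail P(X ≥ n_correct | n, NIR)
  where NIR is the larger class proportion — the accuracy of the best
  label-only predictor.

**Quality gates** (strict inequalities): H > 0.6, kappa > 0.4, balanced
accuracy > 0.7, and — only where an accuracy-vs-NIR test is meaningful,
i.e. training/resampling evaluation — p < 1e-5. External-test reports omit
the p gate.

## y-randomization

Training labels are permuted (identity-equivalent permutations redrawn), the
entire selection pipeline rerun per shuffle, and the shuffled models
evaluated on untouched test data. A genuine structure–label relationship
shows as the true model dominating every shuffle on kappa, balanced accuracy
and H.

## Applicability domain

A query is in-domain iff (a) each of the 12 raw descriptors lies within the
training [min, max], optionally widened by a fraction of the range
(default tolerance 0), and (b) the fraction of the query's fingerprint
on-bits ever set in training is ≥ 0.95. The coverage criterion operationalises
fragment-novelty screening on top of simple range tracking. Reasons list
every violated condition. Widening the tolerance is monotone (never flips
in → out). When consensus models share one featurization they share one
domain; with differing featurizations the intersection rule applies (a
compound must be in-domain for all models). Out-of-domain compounds are
annotated, not predicted — the domain is a trust warning, not a veto on the
chemistry.

## Enumeration

Building blocks are SMILES fragments with dummy-atom attachment points
(`[*:n]` map numbers): caps carry one point on the acyl carbon, amino-acid
residues two (N-terminus, carbonyl carbon). Products are assembled by map-
number fusion (RDKit `molzip`): cap→AA amide, AA→AA peptide bond, terminal
hydroxyl giving the free acid. Pre-merge counts obey n_caps·(n_aa + n_aa²)
with monopeptides (n_caps·n_aa² without); canonically identical products
are merged with all routes kept in the provenance map. The packaged block
file holds 10 caps spanning the naphthalene-ether, tetrahydronaphthalene,
carbazole, fluorenylmethoxycarbonyl, long-alkyl (C13/C15 acyl) and
substituted-aromatic families, plus the 8 amino acids (Gly, Ala, Val, Leu,
Ile, Phe, Met, Tyr), L-configured by default; users supply their own CSV
for other chemistries. 3D structure and synthetic feasibility are out of
scope.

## Consensus screening

For in-domain library members, P(gelator) is averaged over the panel
(raw model probabilities, no recalibration); call = yes iff mean ≥ 0.5
(documented tie-break), and the reported likelihood is the mean probability
of the *called* outcome as a percentage. Candidates are the top-m predicted
gelators and top-m predicted non-gelators by likelihood (defaults 4 and 5)
— a transparent stand-in for manual candidate picking.

## Synthetic data

Experimental gelation labels cannot be redistributed, so all shipped
datasets are generated: a library is enumerated from the packaged blocks,
and labels come from a planted linear-threshold rule on named descriptors —
default **AlogP above the library median**, reflecting that gelation in
this family tracks hydrophobic/aromatic character — XOR independent
Bernoulli(noise) flips. Scores within float noise (1e-9) of the threshold
count as below it, so near-duplicate descriptor values cannot straddle the
boundary. The demo suite draws a 34-compound balanced (17/17) training set
and a disjoint 21-compound (4 gelators / 17 non-gelators) test set at 10%
label noise, matching the real study's class structure; its MODI is ≈ 0.79.

What the generator does *not* emulate: assay noise structure (real
ambiguous, discounted outcomes), concentration and protocol dependence of
gelation, activity cliffs unrelated to hydrophobicity, and the exact
descriptor–label geometry of experimental data. Passing tests therefore
demonstrate that the machinery recovers a knowable planted relationship
under controlled noise — not that gelation itself is predictable to any
particular accuracy.

### Problem sizes used in tests

The recovery benchmark uses a 4-cap × 6-AA library (168 compounds, 5% label
noise, 70/30 split, 3 CV repeats); the full 7-family panel trains in about
two minutes there, and the consensus of the top-3 families by CV H is
required to exceed balanced accuracy 0.9 on the held-out rows. Unit tests
use a 3-cap × 4-AA noise-free library (60 compounds) and the 34/21 demo
suite.

## Numerical choices and edge cases

* ROC ties are grouped before the hull is taken; the hull uses a monotone
  chain with collinear points dropped.
* Beta partial moments use `scipy.stats.beta.cdf` at (a, b) and (a+1, b);
  no quadrature in the production path.
* kappa is an error when chance agreement pₑ = 1 (single-cell matrix);
  balanced accuracy is an error when an actual class is empty.
* Degenerate CV folds cannot occur because training requires ≥ folds
  members per class and splits are stratified; smaller classes fail loudly.
* Constant physchem columns scale by 1 (pass through) rather than dividing
  by zero.
* `SVC(probability=True)` is retained although deprecated upstream: the
  consensus is defined on average probabilities. MLP fits use lbfgs with a
  capped iteration budget; convergence warnings are deliberately silenced
  as regularized small-data fits need not converge to the optimum.

## Known limitations

* The H-measure severity default Beta(2,2) is a convention; rankings of
  models can change under other severities (both parameters configurable).
* PLS-DA probabilities are clipped regression outputs, not calibrated
  probabilities; they are adequate for ranking and consensus averaging.
* The applicability-domain coverage threshold (0.95) is a heuristic; there
  is no universally agreed definition of fingerprint-space domain
  membership.
* MODI uses descriptor space only; datasets separable only in fingerprint
  space will look less modelable than they are.
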