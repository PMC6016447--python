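# gelscreen

QSPR prediction and virtual screening of supramolecular dipeptide
hydrogelators.

Low-molecular-weight gelators (LMWGs) of the functionalised amino-acid /
dipeptide family — an aromatic or long-alkyl *cap* amide-bonded to one or
two amino acids (cap–AA, cap–AA–AA) — self-assemble into fibrous networks
that gel water at sub-weight-percent concentrations. Whether a given
structure gels is notoriously hard to predict: close analogues routinely
differ. `gelscreen` is a toolkit for attacking that problem statistically,
for chemists and cheminformaticians who have a set of tested compounds and
want to search the combinatorial "dipeptide space" *in silico*:

* **featurization** — 12 2D physicochemical descriptors (AlogP, ESOL
  solubility, TPSA, Labute ASA, ring/rotatable-bond counts, MW, HBD/HBA,
  heavy atoms, formal charge) + 1024-bit radius-2 circular fingerprints;
* **modelability** — the MODI index, MODI = ½ Σ_k (fraction of class-k
  compounds whose nearest descriptor-space neighbour shares their label);
  MODI > 0.65 ⇒ worth modelling;
* **model panel** — SVM(RBF), random forest, kNN, neural net, PLS-DA,
  mixed naive Bayes and boosted trees, each tuned by repeated stratified
  5-fold CV maximising **Hand's H measure**
  (H = 1 − E_c[min loss]/E_c[trivial loss], c ~ Beta(2,2)), a coherent
  alternative to AUC;
* **quality gates** — kappa > 0.4, balanced accuracy > 0.7, H > 0.6 and an
  exact binomial no-information-rate test p < 10⁻⁵, all strict;
* **validation** — y-randomization (label shuffling with full pipeline
  reruns) and an applicability domain (training descriptor ranges +
  fingerprint-bit coverage ≥ 0.95);
* **screening** — combinatorial cap–AA(–AA) enumeration from SMILES
  fragments with attachment points, then consensus prediction (average
  P(gelator) across models) over the in-domain library.

All shipped datasets are **synthetic** (planted-rule labels on enumerated
libraries); experimental gelation outcomes are not redistributed. See
`docs/methods.md` for the model details and assumptions.

## Worked example

```python
from gelscreen import Featurizer, build_demo, labels_to_binary, modi

suite = build_demo(seed=0)              # synthetic 17/17 train, 4/17 test
fm = Featurizer().fit_transform(suite.train)
print(modi(fm.physchem, labels_to_binary(suite.train)))
```

Running the narrative scripts in `examples/` prints, for instance:

```text
$ python examples/modelability.py
training set: 34 compounds (17 gelators / 17 non-gelators)
MODI = 0.794
amenable to modelling
```

0.794 > 0.65: in this descriptor space most compounds sit next to a
same-label neighbour, so classification models are worth building.

```text
$ python examples/train_and_evaluate.py
random_forest: resampled H = 0.799 +/- 0.25, best {'max_features': 0.1, 'n_estimators': 200}
boosted_tree: resampled H = 0.646 +/- 0.31, best {'max_depth': 1, 'n_estimators': 100}

external test set (4 gelators / 17 non-gelators):
method           kappa  bal.acc       H      NIR p verdict
random_forest    0.577    0.816   0.499          - not_good
boosted_tree     0.691    0.846   0.517          - not_good
```

The resampled H is the model-selection criterion; the test-set row shows
chance-corrected agreement (kappa), the sensitivity/specificity mean and the
severity-weighted ranking quality on unseen compounds. Here both models
clear kappa and balanced accuracy but fall short of H > 0.6 on the noisy
synthetic test set, so the gate verdict is honest: `not_good`.

```text
$ python examples/virtual_screen.py
enumerated 720 unique compounds; 522 inside the applicability domain
9 candidates (top predicted gelators + top predicted non-gelators by likelihood):
  vl0153  yes (96.2%)  CC(C)[C@H](NC(=O)[C@H](Cc1ccccc1)NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O
  ...
```

720 = 10 caps × (8 + 8²) amino-acid combinations; the 198 out-of-domain
structures get a warning annotation instead of a call, and the % likelihood
is the average model probability of the called outcome.

There is also a thin CLI (`gelscreen featurize|modi|train|evaluate|yrand|
enumerate|screen|pipeline`); `gelscreen pipeline` drives the whole workflow
from a YAML config and writes every stage artifact to disk.

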