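"""Consensus virtual screen of the enumerated library.

Trains a small consensus panel on the demo training set, fits the
applicability domain (descriptor ranges + fingerprint coverage), enumerates
a cap-AA(-AA) library, and reports the top predicted gelators and
non-gelators by average probability.  Out-of-domain compounds get no call,
only an annotation.
"""

from gelscreen import (
    ApplicabilityDomain, Featurizer, ModelConfig, build_demo,
    default_building_blocks, enumerate_library, labels_to_binary,
    repeated_cv_train, screen,
)

suite = build_demo(seed=0)
feat = Featurizer()
fm = feat.fit_transform(suite.train)
y = labels_to_binary(suite.train)

models = [
    repeated_cv_train(fm, y, ModelConfig(family=f, seed=0, repeats=2))[1]
    for f in ("random_forest", "boosted_tree")
]
ad = ApplicabilityDomain.fit(suite.train)

blocks = default_building_blocks()
library = enumerate_library([b for b in blocks if b.kind == "cap"],
                            [b for b in blocks if b.kind == "amino_acid"])

report = screen(library, models, ad, feat, m_gelators=4, m_non_gelators=5)
print(f"enumerated {report.n_enumerated} unique compounds; "
      f"{report.n_in_domain} inside the applicability domain")
print(f"\n{len(report.selected_candidates)} candidates "
      "(top predicted gelators + top predicted non-gelators by likelihood):")
for r in report.selected_candidates:
    print(f"  {r.id}  {r.call:>3} ({r.likelihood:4.1f}%)  {r.smiles}")
# The % likelihood is the average model probability of the called outcome;
# candidates are what one would synthesise and test next.
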