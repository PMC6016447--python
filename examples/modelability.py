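"""Check dataset modelability with MODI before building any model.

MODI is the class-averaged fraction of compounds whose nearest neighbour in
z-scored descriptor space shares their gelation label; above 0.65 the
dataset is considered amenable to classification modelling.
"""

from gelscreen import Featurizer, build_demo, labels_to_binary, modi

suite = build_demo(seed=0)  # synthetic labels from a planted rule, not experimental data
fm = Featurizer().fit_transform(suite.train)
y = labels_to_binary(suite.train)

value = modi(fm.physchem, y)
print(f"training set: {len(suite.train)} compounds "
      f"({int(y.sum())} gelators / {int((1 - y).sum())} non-gelators)")
print(f"MODI = {value:.3f}")
print("amenable to modelling" if value > 0.65 else "below the 0.65 modelability gate")
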