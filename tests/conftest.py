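import numpy as np
import pytest

import gelscreen as g


@pytest.fixture(scope="session")
def blocks():
    return g.default_building_blocks()


@pytest.fixture(scope="session")
def caps(blocks):
    return [b for b in blocks if b.kind == "cap"]


@pytest.fixture(scope="session")
def aas(blocks):
    return [b for b in blocks if b.kind == "amino_acid"]


@pytest.fixture(scope="session")
def demo_suite():
    return g.build_demo(seed=0)


@pytest.fixture(scope="session")
def demo_features(demo_suite):
    """Featurized demo train/test split with frozen training-set scaling."""
    feat = g.Featurizer()
    fm_train = feat.fit_transform(demo_suite.train)
    fm_test = feat.transform(demo_suite.test)
    return {
        "featurizer": feat,
        "fm_train": fm_train,
        "y_train": g.labels_to_binary(demo_suite.train),
        "fm_test": fm_test,
        "y_test": g.labels_to_binary(demo_suite.test),
    }


@pytest.fixture(scope="session")
def small_separable():
    """Noise-free planted-rule dataset: labels are a pure function of AlogP."""
    records = g.generate_fixture_dataset(n_caps=3, n_aas=4, noise=0.0, seed=5)
    feat = g.Featurizer()
    fm = feat.fit_transform(records)
    return records, feat, fm, g.labels_to_binary(records)
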