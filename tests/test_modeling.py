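"""Model panel training, CV selection by H, randomization and consensus."""

import numpy as np
import pytest

import gelscreen as g
from gelscreen.modeling import (
    MixedNB,
    PLSDAClassifier,
    default_grid,
    shuffled_labels,
    top_features,
)


def fast_config(family="pls_da", seed=0, repeats=2):
    return g.ModelConfig(family=family, seed=seed, repeats=repeats)


@pytest.fixture(scope="module")
def separable_split(small_separable):
    """Noise-free planted data split 2:1 into train and held-out rows."""
    records, feat, fm, y = small_separable
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(records))
    tr, te = idx[:40], idx[40:]
    sub = lambda ii: g.FeatureMatrix(
        compound_ids=[fm.compound_ids[i] for i in ii], X=fm.X[ii], names=fm.names,
        center=fm.center, scale=fm.scale, n_bits=fm.n_bits, radius=fm.radius,
    )
    return sub(tr), y[tr], sub(te), y[te]


class TestRepeatedCVTrain:
    def test_noise_free_rule_fit_perfectly(self, separable_split):
        fm, y, _, _ = separable_split
        _, model = g.repeated_cv_train(fm, y, fast_config("random_forest"))
        assert model.evaluation.kappa == 1.0
        assert model.evaluation.balanced_accuracy == 1.0

    def test_same_seed_identical_result(self, separable_split):
        fm, y, _, _ = separable_split
        r1, m1 = g.repeated_cv_train(fm, y, fast_config("pls_da", seed=3))
        r2, m2 = g.repeated_cv_train(fm, y, fast_config("pls_da", seed=3))
        assert r1.per_fold_h == r2.per_fold_h
        assert r1.best_hyperparameters == r2.best_hyperparameters
        np.testing.assert_array_equal(m1.predict_proba(fm), m2.predict_proba(fm))

    def test_selected_point_maximises_mean_h(self, separable_split):
        fm, y, _, _ = separable_split
        result, _ = g.repeated_cv_train(fm, y, fast_config("knn"))
        assert all(result.h_mean >= h - 1e-12 for _, h in result.grid_h_means)

    def test_h_stats_consistent(self, separable_split):
        fm, y, _, _ = separable_split
        result, _ = g.repeated_cv_train(fm, y, fast_config("naive_bayes"))
        assert result.h_mean == pytest.approx(np.mean(result.per_fold_h))
        assert result.h_sd == pytest.approx(np.std(result.per_fold_h, ddof=1))
        assert len(result.per_fold_h) == 5 * 2  # folds x repeats

    def test_small_class_fails_loudly(self, separable_split):
        fm, y, _, _ = separable_split
        y_bad = y.copy()
        y_bad[:] = 0
        y_bad[:3] = 1  # 3 < 5 folds
        with pytest.raises(ValueError, match="stratified"):
            g.repeated_cv_train(fm, y_bad, fast_config())

    def test_low_modi_warns(self, separable_split):
        fm, y, _, _ = separable_split
        with pytest.warns(UserWarning, match="modelable"):
            g.repeated_cv_train(fm, y, fast_config(), modi_value=0.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            g.ModelConfig(family="deep_transformer")


@pytest.fixture(scope="module")
def nb_model(separable_split):
    fm, y, _, _ = separable_split
    return g.repeated_cv_train(fm, y, fast_config("naive_bayes"))[1]


class TestPredictProba:

    def test_probabilities_in_unit_interval(self, nb_model, separable_split):
        _, _, fm_te, _ = separable_split
        p = g.predict_proba(nb_model, fm_te)
        assert np.all((p >= 0) & (p <= 1))

    def test_identical_inputs_identical_outputs(self, nb_model, separable_split):
        _, _, fm_te, _ = separable_split
        np.testing.assert_array_equal(
            g.predict_proba(nb_model, fm_te), g.predict_proba(nb_model, fm_te)
        )

    def test_training_compounds_on_correct_side(self, separable_split):
        fm, y, _, _ = separable_split
        _, model = g.repeated_cv_train(fm, y, fast_config("random_forest"))
        p = g.predict_proba(model, fm)
        assert np.array_equal((p >= 0.5).astype(int), y)

    def test_schema_mismatch_rejected(self, nb_model, separable_split):
        _, _, fm_te, _ = separable_split
        other = g.FeatureMatrix(
            compound_ids=fm_te.compound_ids, X=fm_te.X[:, :100],
            names=fm_te.names[:100], center=fm_te.center[:100],
            scale=fm_te.scale[:100], n_bits=88, radius=3,
        )
        with pytest.raises(ValueError, match="schema"):
            g.predict_proba(nb_model, other)


class TestConsensus:
    class _Fixed:
        """Stub model returning fixed P(gelator)."""

        def __init__(self, p):
            self.p = np.atleast_1d(np.asarray(p, float))
            self.family = "stub"
            self.feature_schema = {"physchem_names": [], "radius": 2, "n_bits": 0}
            self.evaluation = None

        def predict_proba(self, X):
            return np.column_stack([1 - self.p, self.p])

    def _consensus(self, ps):
        models = [
            g.TrainedModel(family="stub", estimator=self._Fixed(p),
                           feature_schema={"physchem_names": [], "radius": 2, "n_bits": 0},
                           best_hyperparameters={})
            for p in ps
        ]
        fm = g.FeatureMatrix(compound_ids=["q"], X=np.zeros((1, 0)), names=[],
                             center=np.zeros(0), scale=np.ones(0), n_bits=0, radius=2)
        calls, lik, mean_p = g.consensus_predict(models, fm)
        return bool(calls[0]), float(lik[0]), float(mean_p[0])

    def test_mean_probability_yes(self):
        call, lik, _ = self._consensus([0.9, 0.8, 0.8])
        assert call is True
        assert lik == pytest.approx(83.333, abs=1e-2)

    def test_complement_symmetry_no(self):
        call, lik, _ = self._consensus([0.1, 0.2, 0.2])
        assert call is False
        assert lik == pytest.approx(83.333, abs=1e-2)

    def test_tie_calls_yes(self):
        call, lik, _ = self._consensus([0.5, 0.5, 0.5])
        assert call is True and lik == 50.0

    def test_identical_models_equal_single(self, separable_split):
        fm, y, fm_te, _ = separable_split
        _, model = g.repeated_cv_train(fm, y, fast_config("naive_bayes"))
        single = g.predict_proba(model, fm_te)
        _, _, mean_p = g.consensus_predict([model, model, model], fm_te)
        np.testing.assert_allclose(mean_p, single, atol=1e-12)

    def test_incompatible_featurization_rejected(self, separable_split):
        fm, y, fm_te, _ = separable_split
        _, m1 = g.repeated_cv_train(fm, y, fast_config("naive_bayes"))
        m2 = g.TrainedModel(family="stub", estimator=None,
                            feature_schema={"physchem_names": [], "radius": 3, "n_bits": 2},
                            best_hyperparameters={})
        with pytest.raises(ValueError, match="incompatible"):
            g.consensus_predict([m1, m2], fm_te)


class TestYRandomization:
    def test_shuffled_labels_never_identity(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1, 0, 1, 1, 0])
        for _ in range(20):
            assert not np.array_equal(shuffled_labels(rng, y), y)

    def test_shuffles_preserve_class_balance(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 7 + [1] * 5)
        assert shuffled_labels(rng, y).sum() == 5

    def test_true_model_beats_every_shuffle(self, separable_split):
        """On noise-free planted data, every label-shuffled model is worse on
        the held-out rows than the true-label model."""
        fm, y, fm_te, y_te = separable_split
        cfg = fast_config("pls_da")
        _, true_model = g.repeated_cv_train(fm, y, cfg)
        p = g.predict_proba(true_model, fm_te)
        true_report = g.evaluate(y_te, (p >= 0.5).astype(int), p)
        reports = g.y_randomization(fm, y, cfg, n_shuffles=5, seed=1,
                                    fm_test=fm_te, y_test=y_te)
        assert len(reports) == 5
        assert all(r.kappa < true_report.kappa for r in reports)

    def test_shuffle_count_validated(self, separable_split):
        fm, y, _, _ = separable_split
        with pytest.raises(ValueError):
            g.y_randomization(fm, y, fast_config(), n_shuffles=0, seed=0)


class TestCustomEstimators:
    def test_plsda_probability_bounds(self, separable_split):
        fm, y, fm_te, _ = separable_split
        est = PLSDAClassifier(n_components=3).fit(fm.X, y)
        p = est.predict_proba(fm_te.X)
        assert np.all((p >= 0) & (p <= 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_mixed_nb_uses_both_blocks(self, separable_split):
        """Zeroing the fingerprint block changes MixedNB posteriors, and so
        does zeroing the physchem block: both likelihoods contribute."""
        fm, y, fm_te, _ = separable_split
        est = MixedNB(n_physchem=fm.n_physchem).fit(fm.X, y)
        base = est.predict_proba(fm_te.X)[:, 1]
        no_fp = fm_te.X.copy()
        no_fp[:, fm.n_physchem:] = 0
        no_phys = fm_te.X.copy()
        no_phys[:, : fm.n_physchem] = 0
        assert not np.allclose(est.predict_proba(no_fp)[:, 1], base)
        assert not np.allclose(est.predict_proba(no_phys)[:, 1], base)

    def test_default_grids_cover_panel(self):
        for fam in g.FAMILIES:
            assert len(default_grid(fam)) >= 1


class TestModelPersistence:
    def test_roundtrip_preserves_predictions(self, nb_model, separable_split, tmp_path):
        _, _, fm_te, _ = separable_split
        path = tmp_path / "model.pkl"
        g.save_model(nb_model, path)
        back = g.load_model(path)
        np.testing.assert_array_equal(
            g.predict_proba(back, fm_te), g.predict_proba(nb_model, fm_te)
        )

    def test_load_refuses_foreign_schema(self, nb_model, tmp_path):
        path = tmp_path / "model.pkl"
        g.save_model(nb_model, path)
        g.load_model(path, expect_schema=nb_model.feature_schema)  # matching: fine
        wrong = dict(nb_model.feature_schema, n_bits=2048)
        with pytest.raises(ValueError, match="schema mismatch"):
            g.load_model(path, expect_schema=wrong)

    def test_load_rejects_non_bundle(self, tmp_path):
        path = tmp_path / "junk.pkl"
        import pickle

        path.write_bytes(pickle.dumps({"something": "else"}))
        with pytest.raises(ValueError, match="not a gelscreen model bundle"):
            g.load_model(path)


class TestFeatureImportance:
    def test_rule_descriptor_ranked_top(self, separable_split):
        """The planted AlogP rule surfaces in the forest's top importances."""
        fm, y, _, _ = separable_split
        _, model = g.repeated_cv_train(fm, y, fast_config("random_forest"))
        assert "alogp" in top_features(model, k=3)

    def test_importance_unavailable_for_knn(self, separable_split):
        fm, y, _, _ = separable_split
        _, model = g.repeated_cv_train(fm, y, fast_config("knn"))
        with pytest.raises(ValueError, match="importance"):
            top_features(model, k=3)
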