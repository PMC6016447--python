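"""Classifier panel: repeated-CV model selection by H measure, y-randomization,
probability prediction and consensus.

Seven model families are trained on the shared feature block (scaled
physchem + binary fingerprints): RBF-kernel SVM, random forest, k-nearest
neighbours, a one-hidden-layer neural network, PLS discriminant analysis, a
mixed naive Bayes (Gaussian on physchem, Bernoulli on fingerprint bits) and
a boosted decision tree.  For each family a small hyperparameter grid is
scanned under repeated stratified 5-fold cross-validation; the grid point
with the largest mean held-out H measure wins and is refit on all training
rows.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .descriptors import FeatureMatrix, N_PHYSCHEM
from .metrics import (
    ConfusionMatrix,
    EvaluationReport,
    evaluate,
    h_measure,
)

class _quiet:
    """Silence upstream noise around estimator calls: the SVC probability
    deprecation (predicted probabilities are what the average-probability
    consensus is defined on) and MLP convergence chatter (regularized
    small-data fits need not fully converge)."""

    def __enter__(self):
        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.filterwarnings(
            "ignore", message="The `probability` parameter was deprecated"
        )
        warnings.simplefilter("ignore", ConvergenceWarning)

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


FAMILIES = (
    "svm_rbf",
    "random_forest",
    "knn",
    "neural_net",
    "pls_da",
    "naive_bayes",
    "boosted_tree",
)

#: the three families the consensus screen uses by default
CONSENSUS_FAMILIES = ("svm_rbf", "random_forest", "neural_net")


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS regression on a 0/1 response used as a discriminant classifier.

    The continuous PLS prediction is clipped to [0, 1] and read as
    P(gelator); calls use the 0.5 threshold.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        k = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=k)
        self.pls_.fit(X, np.asarray(y, float))
        return self

    def predict_proba(self, X):
        p1 = np.clip(self.pls_.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class MixedNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes for the mixed feature block.

    Gaussian likelihood on the first ``n_physchem`` (scaled, continuous)
    columns, Bernoulli on the remaining binary fingerprint columns; the two
    log-likelihoods are summed and the class prior counted once.
    """

    def __init__(self, n_physchem: int = N_PHYSCHEM, alpha: float = 1.0):
        self.n_physchem = n_physchem
        self.alpha = alpha

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.gnb_ = GaussianNB().fit(X[:, : self.n_physchem], y)
        self.bnb_ = BernoulliNB(alpha=self.alpha).fit(X[:, self.n_physchem :], y)
        return self

    def predict_proba(self, X):
        log_joint = (
            self.gnb_.predict_log_proba(X[:, : self.n_physchem])
            + self.bnb_.predict_log_proba(X[:, self.n_physchem :])
        )  # prior enters twice via the per-block posteriors ...
        log_prior = np.log(self.gnb_.class_prior_)
        log_joint -= log_prior  # ... so remove one copy
        log_joint -= log_joint.max(axis=1, keepdims=True)
        p = np.exp(log_joint)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def default_grid(family: str) -> list[dict]:
    grids = {
        "svm_rbf": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.001, 0.01]},
        "random_forest": {"n_estimators": [200], "max_features": ["sqrt", 0.1]},
        "knn": {"n_neighbors": [3, 5, 7, 9]},
        "neural_net": {"hidden_layer_sizes": [(8,), (16,)], "alpha": [1e-3, 1e-1]},
        "pls_da": {"n_components": [2, 3, 5, 8]},
        "naive_bayes": {"alpha": [0.5, 1.0]},
        "boosted_tree": {"n_estimators": [100], "max_depth": [1, 3]},
    }
    return list(ParameterGrid(grids[family]))


def build_estimator(family: str, params: dict, seed: int, n_physchem: int = N_PHYSCHEM):
    if family == "svm_rbf":
        return SVC(probability=True, random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "neural_net":
        return MLPClassifier(solver="lbfgs", max_iter=500, random_state=seed, **params)
    if family == "pls_da":
        return PLSDAClassifier(**params)
    if family == "naive_bayes":
        return MixedNB(n_physchem=n_physchem, **params)
    if family == "boosted_tree":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


@dataclass
class ModelConfig:
    family: str
    hyperparameter_grid: list[dict] | None = None  # None -> default grid
    seed: int = 0
    folds: int = 5
    repeats: int = 10

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")

    @property
    def grid(self) -> list[dict]:
        return self.hyperparameter_grid or default_grid(self.family)


@dataclass
class CVResult:
    family: str
    best_hyperparameters: dict
    h_mean: float
    h_sd: float
    per_fold_h: list[float]
    resampled_confusions: list[ConfusionMatrix]
    grid_h_means: list[tuple[dict, float]] = field(default_factory=list)


@dataclass
class TrainedModel:
    family: str
    estimator: object
    feature_schema: dict
    best_hyperparameters: dict
    evaluation: EvaluationReport | None = None

    def predict_proba(self, fm: FeatureMatrix) -> np.ndarray:
        return predict_proba(self, fm)


def _check_schema(model: TrainedModel, fm: FeatureMatrix) -> None:
    schema = {
        "physchem_names": fm.names[: fm.n_physchem],
        "radius": fm.radius,
        "n_bits": fm.n_bits,
    }
    if schema != model.feature_schema:
        raise ValueError(
            f"feature schema mismatch: model expects {model.feature_schema}, got {schema}"
        )


def predict_proba(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """P(gelator) for each row of a query feature matrix."""
    _check_schema(model, fm)
    expected = len(model.feature_schema["physchem_names"]) + model.feature_schema["n_bits"]
    if fm.X.shape[1] != expected:
        raise ValueError(f"feature dimension {fm.X.shape[1]} != expected {expected}")
    with _quiet():
        return model.estimator.predict_proba(fm.X)[:, 1]


def repeated_cv_train(
    fm: FeatureMatrix,
    y: np.ndarray,
    config: ModelConfig,
    modi_value: float | None = None,
) -> tuple[CVResult, TrainedModel]:
    """Select hyperparameters by mean held-out H under repeated stratified CV.

    Ties in mean H go to the earlier grid point.  The winning point is refit
    on all rows and evaluated on the training set itself (with the exact
    binomial NIR test), matching how resampling and training-set statistics
    are reported side by side.
    """
    y = np.asarray(y, int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < config.folds:
        raise ValueError(
            f"each class needs >= {config.folds} members for stratified "
            f"{config.folds}-fold CV; got {class_counts.tolist()}"
        )
    if modi_value is not None and modi_value <= 0.65:
        warnings.warn(
            f"MODI = {modi_value:.2f} <= 0.65: data may not be modelable",
            stacklevel=2,
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=config.folds, n_repeats=config.repeats, random_state=config.seed
    )
    splits = list(splitter.split(fm.X, y))
    grid_results = []
    for params in config.grid:
        fold_h, fold_cm = [], []
        for train_idx, test_idx in splits:
            est = build_estimator(config.family, params, config.seed, fm.n_physchem)
            with _quiet():
                est.fit(fm.X[train_idx], y[train_idx])
                p = est.predict_proba(fm.X[test_idx])[:, 1]
            fold_h.append(h_measure(p, y[test_idx]))
            fold_cm.append(
                ConfusionMatrix.from_predictions(y[test_idx], (p >= 0.5).astype(int))
            )
        grid_results.append((params, fold_h, fold_cm))

    best_params, best_h, best_cm = max(
        grid_results, key=lambda t: np.mean(t[1])
    )  # max() keeps the first of tied points
    result = CVResult(
        family=config.family,
        best_hyperparameters=best_params,
        h_mean=float(np.mean(best_h)),
        h_sd=float(np.std(best_h, ddof=1)),
        per_fold_h=[float(h) for h in best_h],
        resampled_confusions=best_cm,
        grid_h_means=[(p, float(np.mean(h))) for p, h, _ in grid_results],
    )
    final = build_estimator(config.family, best_params, config.seed, fm.n_physchem)
    with _quiet():
        final.fit(fm.X, y)
    model = TrainedModel(
        family=config.family,
        estimator=final,
        feature_schema={
            "physchem_names": fm.names[: fm.n_physchem],
            "radius": fm.radius,
            "n_bits": fm.n_bits,
        },
        best_hyperparameters=best_params,
    )
    p_train = model.predict_proba(fm)
    model.evaluation = evaluate(y, (p_train >= 0.5).astype(int), p_train, with_nir=True)
    return result, model


def train_panel(
    fm: FeatureMatrix,
    y: np.ndarray,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    repeats: int = 10,
    modi_value: float | None = None,
) -> dict[str, tuple[CVResult, TrainedModel]]:
    """Run repeated-CV selection for each requested family."""
    return {
        fam: repeated_cv_train(
            fm, y, ModelConfig(family=fam, seed=seed, repeats=repeats), modi_value
        )
        for fam in families
    }


def shuffled_labels(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Permute labels, redrawing until the permuted vector differs from ``y``
    on at least one compound (identity-equivalent permutations excluded)."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot shuffle a single-class label vector meaningfully")
    while True:
        y_shuf = y[rng.permutation(len(y))]
        if not np.array_equal(y_shuf, y):
            return y_shuf


def y_randomization(
    fm: FeatureMatrix,
    y: np.ndarray,
    config: ModelConfig,
    n_shuffles: int,
    seed: int,
    fm_test: FeatureMatrix | None = None,
    y_test: np.ndarray | None = None,
) -> list[EvaluationReport]:
    """Rerun the full selection pipeline on label-shuffled training data.

    Each shuffle permutes the training labels (identity permutations are
    redrawn), repeats hyperparameter selection and refitting, and evaluates
    on the untouched test set when one is supplied (otherwise on the
    training rows against their shuffled labels).  True models should beat
    every shuffled one by a wide margin.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, int)
    reports = []
    for _ in range(n_shuffles):
        y_shuf = shuffled_labels(rng, y)
        _, model = repeated_cv_train(fm, y_shuf, config)
        if fm_test is not None and y_test is not None:
            p = model.predict_proba(fm_test)
            reports.append(
                evaluate(y_test, (p >= 0.5).astype(int), p, with_nir=False)
            )
        else:
            reports.append(model.evaluation)
    return reports


def consensus_predict(
    models: list[TrainedModel], fm: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average P(gelator) over models; call yes when the mean is >= 0.5.

    Returns (calls, likelihood_percent, mean_p): the reported likelihood is
    the mean probability of the *called* outcome, as a percentage — the mean
    P(gelator) for a yes call, its complement for a no call.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    schemas = {repr(m.feature_schema) for m in models}
    if len(schemas) != 1:
        raise ValueError("models have incompatible featurizations")
    probs = np.vstack([predict_proba(m, fm) for m in models])
    mean_p = probs.mean(axis=0)
    calls = mean_p >= 0.5
    likelihood = np.where(calls, mean_p, 1.0 - mean_p) * 100.0
    return calls, likelihood, mean_p


_BUNDLE_FORMAT = "gelscreen-model-v1"


def _config_hash(model: TrainedModel) -> str:
    blob = repr((model.family, model.best_hyperparameters, model.feature_schema))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model bundle (estimator, feature schema,
    hyperparameters, config hash)."""
    with open(path, "wb") as fh:
        pickle.dump(
            {"format": _BUNDLE_FORMAT, "config_hash": _config_hash(model), "model": model},
            fh,
        )


def load_model(path, expect_schema: dict | None = None) -> TrainedModel:
    """Load a model bundle; refuses bundles whose feature schema differs
    from ``expect_schema`` (e.g. a Featurizer's ``schema``)."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or payload.get("format") != _BUNDLE_FORMAT:
        raise ValueError(f"{path}: not a gelscreen model bundle")
    model: TrainedModel = payload["model"]
    if payload.get("config_hash") != _config_hash(model):
        raise ValueError(f"{path}: bundle config hash mismatch (corrupted bundle?)")
    if expect_schema is not None and expect_schema != model.feature_schema:
        raise ValueError(
            f"feature schema mismatch: bundle carries {model.feature_schema}, "
            f"expected {expect_schema}"
        )
    return model


def top_features(model: TrainedModel, k: int = 3) -> list[str]:
    """Feature names ranked by importance, for tree-ensemble families."""
    imp = getattr(model.estimator, "feature_importances_", None)
    if imp is None:
        raise ValueError(f"{model.family} does not expose feature importances")
    names = model.feature_schema["physchem_names"] + [
        f"fp{i}" for i in range(model.feature_schema["n_bits"])
    ]
    order = np.argsort(-imp)
    return [names[i] for i in order[:k]]
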