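"""Classifier training: algorithm registry, repeated stratified CV, and
random hyperparameter search scored by AUC.

The registry covers the classical algorithms used for this problem —
logistic regression, LDA, decision tree, SVM (linear / polynomial / RBF
kernels), Gaussian naive Bayes, a one-hidden-layer neural network, and a
random forest — each with a finite or bounded hyperparameter space sampled
uniformly (log-uniformly for scale parameters). Model selection maximizes
the mean validation AUC over folds x repeats.

Class-imbalance resampling interacts with cross-validation in two modes:
``leaky=False`` (default) resamples inside each training fold only, so no
synthetic or duplicated row ever shares information with its validation
fold; ``leaky=True`` resamples the whole training set before splitting,
which lets resampled copies of validation rows into training and inflates
the apparent CV performance on imbalanced data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from dilipred.metrics import auc
from dilipred.prep import FeatureMatrix, ResampleConfig, resample

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One registry entry: estimator factory plus its search space.

    Space entries are ("loguniform", lo, hi), ("int", lo, hi) (inclusive) or
    ("choice", [options]).
    """

    id: str
    make: Callable[..., object]
    space: dict[str, tuple]

    def sample_params(self, rng: np.random.Generator) -> dict:
        params = {}
        for name, spec in self.space.items():
            kind = spec[0]
            if kind == "loguniform":
                lo, hi = spec[1], spec[2]
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            elif kind == "int":
                params[name] = int(rng.integers(spec[1], spec[2] + 1))
            elif kind == "choice":
                params[name] = spec[1][int(rng.integers(len(spec[1])))]
            else:
                raise ValueError(f"unknown space kind {kind!r}")
        return params


def _make_mlp(hidden_units=5, alpha=1e-3, random_state=None):
    return MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        alpha=alpha,
        max_iter=500,
        random_state=random_state,
    )


ALGORITHMS: dict[str, AlgorithmSpec] = {
    spec.id: spec
    for spec in [
        AlgorithmSpec(
            "logistic_regression",
            lambda C=1.0, random_state=None: LogisticRegression(C=C, max_iter=2000),
            {"C": ("loguniform", 1e-3, 1e3)},
        ),
        AlgorithmSpec(
            "lda",
            lambda solver="svd", random_state=None: LinearDiscriminantAnalysis(solver=solver),
            {"solver": ("choice", ["svd", "lsqr"])},
        ),
        AlgorithmSpec(
            "decision_tree",
            lambda max_depth=5, random_state=None: DecisionTreeClassifier(
                max_depth=max_depth, random_state=random_state
            ),
            {"max_depth": ("int", 1, 10)},
        ),
        AlgorithmSpec(
            "svm_linear",
            lambda C=1.0, random_state=None: SVC(
                kernel="linear", C=C, probability=True, random_state=random_state
            ),
            {"C": ("loguniform", 1e-3, 1e3)},
        ),
        AlgorithmSpec(
            "svm_poly",
            lambda C=1.0, degree=2, random_state=None: SVC(
                kernel="poly", C=C, degree=degree, probability=True, random_state=random_state
            ),
            {"C": ("loguniform", 1e-3, 1e3), "degree": ("choice", [2, 3])},
        ),
        AlgorithmSpec(
            "svm_rbf",
            lambda C=1.0, gamma=0.1, random_state=None: SVC(
                kernel="rbf", C=C, gamma=gamma, probability=True, random_state=random_state
            ),
            {"C": ("loguniform", 1e-3, 1e3), "gamma": ("loguniform", 1e-4, 1e1)},
        ),
        AlgorithmSpec(
            "naive_bayes",
            lambda var_smoothing=1e-9, random_state=None: GaussianNB(var_smoothing=var_smoothing),
            {"var_smoothing": ("loguniform", 1e-12, 1e-6)},
        ),
        AlgorithmSpec(
            "nnet_1hidden",
            _make_mlp,
            {"hidden_units": ("int", 1, 10), "alpha": ("loguniform", 1e-5, 1e0)},
        ),
        AlgorithmSpec(
            "random_forest",
            lambda n_estimators=200, max_depth=None, random_state=None: RandomForestClassifier(
                n_estimators=n_estimators, max_depth=max_depth, random_state=random_state
            ),
            {"n_estimators": ("int", 100, 500), "max_depth": ("choice", [None, 3, 5, 10])},
        ),
    ]
}


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and random-search settings.

    The study protocol is 5-fold CV repeated 100 times; the default here is
    5 repeats for desk-scale runs, with the full value available via config.
    """

    folds: int = 5
    repeats: int = 5
    n_candidates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1 or self.n_candidates < 1:
            raise ValueError("invalid CV configuration")


@dataclass
class TrainedModel:
    """A fitted classifier with its cross-validated AUC and provenance."""

    algorithm: str
    params: dict
    cv_auc: float
    estimator: object
    columns: list[str]
    dataset: str = ""
    dili_class: str = ""
    seed: int = 0

    def metadata(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": {k: repr(v) for k, v in self.params.items()},
            "cv_auc": self.cv_auc,
            "dataset": self.dataset,
            "dili_class": self.dili_class,
            "seed": self.seed,
            "n_features": len(self.columns),
        }


def stratified_folds(labels: pd.Series, k: int, seed: int) -> pd.Series:
    """Per-drug fold assignment (0..k-1), stratified by class."""
    y = labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    assign = np.empty(len(y), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assign[val_idx] = fold
    return pd.Series(assign, index=labels.index)


def _fit_candidate(alg: AlgorithmSpec, params: dict, x: np.ndarray, y: np.ndarray, seed: int):
    est = alg.make(**params, random_state=seed % (2**31))
    with warnings.catch_warnings():
        # SVC(probability=True) deprecation and MLP non-convergence on tiny
        # candidate draws are expected during random search
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x, y)
    return est

def _proba_pos(est, x: np.ndarray) -> np.ndarray:
    probs = est.predict_proba(x)
    pos_col = list(est.classes_).index(1)
    return probs[:, pos_col]


def _cv_auc(
    alg: AlgorithmSpec,
    params: dict,
    fm: FeatureMatrix,
    cv: CVConfig,
    rs: ResampleConfig,
    leaky: bool,
) -> float:
    """Mean validation AUC over folds x repeats for one hyperparameter draw."""
    work = resample(fm, rs) if leaky else fm
    x_all, y_all = work.X.to_numpy(), work.y.to_numpy()
    aucs = []
    for rep in range(cv.repeats):
        folds = stratified_folds(work.y, cv.folds, seed=cv.seed + 7919 * rep)
        for f in range(cv.folds):
            val = folds.to_numpy() == f
            x_tr, y_tr = x_all[~val], y_all[~val]
            if not leaky and rs.method != "none":
                tr_fm = FeatureMatrix(
                    X=work.X.loc[~val], y=work.y.loc[~val], name=work.name
                )
                tr_fm = resample(tr_fm, rs)
                x_tr, y_tr = tr_fm.X.to_numpy(), tr_fm.y.to_numpy()
            if len(np.unique(y_all[val])) < 2 or len(np.unique(y_tr)) < 2:
                log.warning("degenerate fold skipped (single class)")
                continue
            est = _fit_candidate(alg, params, x_tr, y_tr, seed=cv.seed)
            aucs.append(auc(_proba_pos(est, x_all[val]), y_all[val]))
    if not aucs:
        raise ValueError("all cross-validation folds were degenerate")
    return float(np.mean(aucs))


def random_search_cv(
    fm: FeatureMatrix,
    alg: AlgorithmSpec | str,
    cv: CVConfig = CVConfig(),
    rs: ResampleConfig = ResampleConfig(),
    leaky: bool = False,
) -> TrainedModel:
    """Random hyperparameter search under repeated stratified CV.

    Draws ``cv.n_candidates`` configurations uniformly from the algorithm's
    space, scores each by mean validation AUC, and refits the best (ties: the
    first drawn) on the full training data (resampled per the same policy).
    """
    if isinstance(alg, str):
        alg = ALGORITHMS[alg]
    if fm.y.nunique() < 2:
        raise ValueError("training requires both classes")
    rng = np.random.default_rng(cv.seed)
    candidates = [alg.sample_params(rng) for _ in range(cv.n_candidates)]
    best_params, best_auc = None, -np.inf
    for params in candidates:
        score = _cv_auc(alg, params, fm, cv, rs, leaky)
        if score > best_auc:
            best_params, best_auc = params, score
    final_fm = resample(fm, rs)
    est = _fit_candidate(
        alg, best_params, final_fm.X.to_numpy(), final_fm.y.to_numpy(), seed=cv.seed
    )
    return TrainedModel(
        algorithm=alg.id,
        params=best_params,
        cv_auc=best_auc,
        estimator=est,
        columns=list(fm.X.columns),
        dataset=fm.name,
        seed=cv.seed,
    )


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Class-probability pairs for each drug; columns must match training."""
    missing = [c for c in model.columns if c not in features.columns]
    extra = [c for c in features.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(f"feature columns mismatch: missing={missing}, extra={extra}")
    x = features[model.columns].to_numpy()
    pos = _proba_pos(model.estimator, x)
    return pd.DataFrame(
        {"p_negative": 1.0 - pos, "p_positive": pos}, index=features.index
    )


def rank_models(models: list[TrainedModel], k: int) -> list[TrainedModel]:
    """Top-k models by cv_auc, descending; ties by (algorithm, dataset)."""
    if not models:
        raise ValueError("no models to rank")
    ordered = sorted(models, key=lambda m: (-m.cv_auc, m.algorithm, m.dataset))
    return ordered[: min(k, len(ordered))]
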