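"""Partner-local ("teacher") classifiers: zoo, HPO, cross-validation.

Eleven classification architectures are exposed through one contract:
construct by name, fit, and emit a positive-class probability. Margin
classifiers without native probabilities (SVC) are wrapped with a
monotone logistic calibration of their decision values fitted on the
training data, because downstream decidability scoring needs
probabilities.

Hyperparameter optimization follows a budgeted search over per-architecture
spaces, scored on mean cross-validated balanced accuracy with sensitivity
as the tie-breaker among near-optimal configurations. A Bayesian search
engine is used when the optional backend is importable; otherwise a
seeded random search over the same space runs within the same budget,
and the engine actually used is recorded in the result.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .chem_features import FeatureMatrix, ScalerState
from .evaluation import classification_metrics, confusion_counts

__all__ = [
    "ARCHITECTURES",
    "TrainedClassifier",
    "CVReport",
    "HPOResult",
    "make_classifier",
    "default_search_space",
    "optimize_hyperparameters",
    "cross_validate",
    "oversample_minority",
    "train_teacher",
    "save_bundle",
    "load_bundle",
]


class MarginCalibratedClassifier(BaseEstimator, ClassifierMixin):
    """Wrap a margin classifier with Platt-style probability calibration.

    Fits the base estimator, then a 1-d logistic regression mapping its
    decision values (on the training data) to probabilities.
    """

    def __init__(self, base, seed: int = 0):
        self.base = base
        self.seed = seed

    def fit(self, X, y):
        self.base_ = clone(self.base).fit(X, y)
        z = self.base_.decision_function(X).reshape(-1, 1)
        self.calibrator_ = LogisticRegression(random_state=self.seed).fit(z, y)
        self.classes_ = self.calibrator_.classes_
        return self

    def predict_proba(self, X):
        z = self.base_.decision_function(X).reshape(-1, 1)
        return self.calibrator_.predict_proba(z)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_xgb(params: dict, seed: int):
    from xgboost import XGBClassifier

    # defaults selected by internal cross-validation on synthetic training
    # sets: shallow trees with a slow learning rate generalize best on the
    # sparse fingerprint block
    return XGBClassifier(
        n_estimators=params.get("n_estimators", 600),
        max_depth=params.get("max_depth", 3),
        learning_rate=params.get("learning_rate", 0.05),
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )


def _zoo() -> dict:
    return {
        "gnb": lambda p, s: GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9)),
        "sgd": lambda p, s: SGDClassifier(
            loss="log_loss", alpha=p.get("alpha", 1e-4),
            penalty=p.get("penalty", "l2"), max_iter=2000, tol=1e-4, random_state=s,
        ),
        "dt": lambda p, s: DecisionTreeClassifier(
            max_depth=p.get("max_depth"), min_samples_leaf=p.get("min_samples_leaf", 1),
            random_state=s,
        ),
        "rf": lambda p, s: RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100), max_depth=p.get("max_depth"),
            max_features=p.get("max_features", "sqrt"), n_jobs=1, random_state=s,
        ),
        "et": lambda p, s: ExtraTreesClassifier(
            n_estimators=p.get("n_estimators", 100), max_depth=p.get("max_depth"),
            n_jobs=1, random_state=s,
        ),
        "knn": lambda p, s: KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5), weights=p.get("weights", "uniform"),
        ),
        "mlp": lambda p, s: MLPClassifier(
            hidden_layer_sizes=p.get("hidden_layer_sizes", (64,)),
            alpha=p.get("alpha", 0.3),
            learning_rate_init=p.get("learning_rate_init", 1e-3),
            max_iter=p.get("max_iter", 400), random_state=s,
        ),
        "ab": lambda p, s: AdaBoostClassifier(
            n_estimators=p.get("n_estimators", 50),
            learning_rate=p.get("learning_rate", 1.0), random_state=s,
        ),
        "gb": lambda p, s: GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 50),
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 3), max_features="sqrt", random_state=s,
        ),
        "svc": lambda p, s: MarginCalibratedClassifier(
            SVC(C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
                kernel=p.get("kernel", "rbf"), random_state=s),
            seed=s,
        ),
        "xgb": _make_xgb,
    }


ARCHITECTURES = tuple(sorted(_zoo()))

_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "gnb": {"var_smoothing": [1e-11, 1e-9, 1e-7]},
    "sgd": {"alpha": [1e-5, 1e-4, 1e-3], "penalty": ["l2", "l1"]},
    "dt": {"max_depth": [None, 4, 8, 16], "min_samples_leaf": [1, 3, 10]},
    "rf": {"n_estimators": [100, 200], "max_depth": [None, 8, 16], "max_features": ["sqrt", 0.1]},
    "et": {"n_estimators": [100, 200], "max_depth": [None, 8, 16]},
    "knn": {"n_neighbors": [3, 5, 11], "weights": ["uniform", "distance"]},
    "mlp": {"hidden_layer_sizes": [(64,), (128,), (64, 32)], "alpha": [1e-2, 1e-1, 1.0],
            "learning_rate_init": [1e-3, 3e-4]},
    "ab": {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
    "gb": {"n_estimators": [50, 100], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
    "svc": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01], "kernel": ["rbf", "linear"]},
    "xgb": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
}


def default_search_space(architecture: str) -> dict[str, list]:
    if architecture not in _SEARCH_SPACES:
        raise ValueError(f"unknown architecture {architecture!r}; zoo: {ARCHITECTURES}")
    return {k: list(v) for k, v in _SEARCH_SPACES[architecture].items()}


def make_classifier(architecture: str, hyperparameters: dict | None = None, seed: int = 0):
    """Construct a zoo classifier by name under the uniform contract."""
    zoo = _zoo()
    if architecture not in zoo:
        raise ValueError(f"unknown architecture {architecture!r}; zoo: {ARCHITECTURES}")
    return zoo[architecture](hyperparameters or {}, seed)


def _as_xy(features, labels=None):
    if isinstance(features, FeatureMatrix):
        X = features.X
        y = features.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels)
    return X, y


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class: {classes.tolist()}")


def cv_folds(y: np.ndarray, scheme: str, k: int, repeats: int, seed: int):
    """Fold assignments depending only on (seed, n, labels, scheme).

    Stable across architectures so model comparisons share folds.
    """
    if scheme == "stratified":
        for label in np.unique(y):
            if np.sum(y == label) < k:
                raise ValueError(f"class {label} has fewer than k={k} members")
        splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    elif scheme == "random":
        splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    if len(y) < k:
        raise ValueError(f"n={len(y)} smaller than k={k}")
    return list(splitter.split(np.zeros((len(y), 1)), y))


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, pos_col]


def _fold_metrics(model, X, y, train_idx, test_idx) -> dict[str, float]:
    model.fit(X[train_idx], y[train_idx])
    p = _positive_proba(model, X[test_idx])
    pred = (p >= 0.5).astype(int)
    m = classification_metrics(confusion_counts(y[test_idx], pred))
    try:
        m["auc"] = roc_auc_score(y[test_idx], p)
    except ValueError:
        m["auc"] = float("nan")
    return m


@dataclass
class CVReport:
    """Per-fold metrics plus mean +/- sd aggregates for one architecture."""

    folds: pd.DataFrame
    scheme: str
    k: int
    repeats: int
    architecture: str
    seed: int

    METRICS = ("balanced_accuracy", "specificity", "sensitivity", "precision", "auc", "mcc")

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.folds[m].mean()) for m in self.METRICS}

    @property
    def sd(self) -> dict[str, float]:
        return {m: float(self.folds[m].std(ddof=1)) for m in self.METRICS}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def cross_validate(
    features, labels=None, architecture: str = "rf", hyperparameters: dict | None = None,
    scheme: str = "stratified", k: int = 5, repeats: int = 10, seed: int = 0,
) -> CVReport:
    """Repeated k-fold CV; every record is tested exactly once per repeat."""
    X, y = _as_xy(features, labels)
    _check_two_classes(y)
    folds = cv_folds(y, scheme, k, repeats, seed)
    rows = []
    for fold_i, (tr, te) in enumerate(folds):
        model = make_classifier(architecture, hyperparameters, seed)
        m = _fold_metrics(model, X, y, tr, te)
        m.update({"fold": fold_i % k, "repeat": fold_i // k})
        rows.append(m)
    return CVReport(
        folds=pd.DataFrame(rows), scheme=scheme, k=k, repeats=repeats,
        architecture=architecture, seed=seed,
    )


@dataclass
class HPOResult:
    best_params: dict
    best_balanced_accuracy: float
    best_sensitivity: float
    trials: pd.DataFrame
    engine: str
    budget: int
    seed: int


def _space_grid(space: dict[str, list]) -> list[dict]:
    keys = list(space)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(space[k] for k in keys))]


def _sample_configs(space: dict[str, list], budget: int, seed: int) -> list[dict]:
    grid = _space_grid(space)
    if budget >= len(grid):
        return grid
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=budget, replace=False)
    return [grid[i] for i in sorted(idx)]


def select_best_trial(trials: pd.DataFrame, tolerance: float = 1e-6) -> int:
    """Winning trial index: best mean balanced accuracy, with mean
    sensitivity breaking ties among configurations within ``tolerance``
    of the best. Earlier trials win exact double ties (stable sort)."""
    best_ba = trials["balanced_accuracy"].max()
    near = trials[trials["balanced_accuracy"] >= best_ba - tolerance]
    winner = near.sort_values(
        ["sensitivity", "balanced_accuracy"], ascending=False, kind="stable"
    ).iloc[0]
    return int(winner.name)


def optimize_hyperparameters(
    features, labels=None, architecture: str = "rf", budget: int = 25,
    k: int = 5, n_repeats: int = 10, seed: int = 0, space: dict | None = None,
) -> HPOResult:
    """Budgeted hyperparameter search scored on CV balanced accuracy.

    Among configurations within 1e-6 of the best mean balanced accuracy,
    the one with the highest mean sensitivity wins; re-optimizing on
    sensitivity alone would collapse to always-positive classifiers, so
    sensitivity acts only as the tie-breaker. Deterministic given seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X, y = _as_xy(features, labels)
    _check_two_classes(y)
    space = space or default_search_space(architecture)
    folds = cv_folds(y, "stratified", k, n_repeats, seed)

    def evaluate(params: dict) -> tuple[float, float]:
        bas, sens = [], []
        for tr, te in folds:
            model = make_classifier(architecture, params, seed)
            m = _fold_metrics(model, X, y, tr, te)
            bas.append(m["balanced_accuracy"])
            sens.append(m["sensitivity"])
        return float(np.nanmean(bas)), float(np.nanmean(sens))

    engine = "random"
    try:  # optional Bayesian backend
        import skopt  # noqa: F401

        engine = "bayes"
    except ImportError:
        pass

    rows = []
    if engine == "bayes":
        from skopt import Optimizer
        from skopt.space import Categorical

        grid = _space_grid(space)
        opt = Optimizer([Categorical(list(range(len(grid))))], random_state=seed)
        candidates = []
        for _ in range(min(budget, len(grid))):
            idx = opt.ask()[0]
            params = grid[idx]
            ba, se = evaluate(params)
            opt.tell([idx], -ba)
            candidates.append(params)
            rows.append(
                {"params": json.dumps(params, default=str),
                 "balanced_accuracy": ba, "sensitivity": se}
            )
    else:
        candidates = _sample_configs(space, budget, seed)
        for params in candidates:
            ba, se = evaluate(params)
            rows.append(
                {"params": json.dumps(params, default=str),
                 "balanced_accuracy": ba, "sensitivity": se}
            )
    trials = pd.DataFrame(rows)
    winner_idx = select_best_trial(trials)
    winner = trials.loc[winner_idx]
    best_params = candidates[winner_idx]
    return HPOResult(
        best_params=best_params,
        best_balanced_accuracy=float(winner["balanced_accuracy"]),
        best_sensitivity=float(winner["sensitivity"]),
        trials=trials, engine=engine, budget=budget, seed=seed,
    )


def oversample_minority(features, labels=None, target_ratio: float = 1.0, seed: int = 0):
    """Replicate whole minority rows until minority/majority approaches
    ``target_ratio`` as closely as integer replication allows without
    exceeding it. The majority class is untouched; no synthetic rows.
    """
    X, y = _as_xy(features, labels)
    _check_two_classes(y)
    counts = {c: int(np.sum(y == c)) for c in (0, 1)}
    minority = 0 if counts[0] < counts[1] else 1
    n_min, n_maj = counts[minority], counts[1 - minority]
    factor = max(1, int(np.floor(target_ratio * n_maj / n_min)))
    if factor == 1:
        return X.copy(), y.copy()
    min_idx = np.flatnonzero(y == minority)
    extra = np.tile(min_idx, factor - 1)
    X_out = np.vstack([X, X[extra]])
    y_out = np.concatenate([y, y[extra]])
    return X_out, y_out


@dataclass
class TrainedClassifier:
    """A fitted model plus the training-space reference needed downstream.

    ``training_fingerprints`` back reliability scoring; ``config_hash``
    guards against mixing feature spaces at prediction time.
    """

    architecture: str
    model: object
    training_fingerprints: np.ndarray
    config_hash: str
    label_counts: dict[int, int]
    hyperparameters: dict
    seed: int
    scaler: ScalerState | None = None
    variant: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.training_fingerprints is None or len(self.training_fingerprints) == 0:
            raise ValueError("training-space reference must be non-empty")

    def predict_proba_positive(self, features) -> np.ndarray:
        """Positive-class probability for each row; checks feature config."""
        if isinstance(features, FeatureMatrix):
            if features.config_hash != self.config_hash:
                raise ValueError(
                    f"feature-config mismatch: model {self.config_hash!r} "
                    f"vs data {features.config_hash!r}"
                )
            X = features.X
        else:
            X = np.asarray(features, dtype=np.float64)
        return np.clip(_positive_proba(self.model, X), 0.0, 1.0)

    def predict(self, features) -> np.ndarray:
        return (self.predict_proba_positive(features) >= 0.5).astype(np.int64)


def train_teacher(
    partner_train: FeatureMatrix,
    architecture: str = "rf",
    hyperparameters: dict | None = None,
    seed: int = 0,
    oversample_ratio: float | None = None,
    scaler: ScalerState | None = None,
    variant: str = "",
) -> TrainedClassifier:
    """Fit one partner-local classifier on its private training set."""
    X, y = partner_train.X, partner_train.labels
    _check_two_classes(y)
    if oversample_ratio is not None:
        X, y = oversample_minority(X, y, target_ratio=oversample_ratio, seed=seed)
    model = make_classifier(architecture, hyperparameters, seed)
    model.fit(X, y)
    return TrainedClassifier(
        architecture=architecture,
        model=model,
        training_fingerprints=partner_train.fingerprints.copy(),
        config_hash=partner_train.config_hash,
        label_counts={0: int(np.sum(y == 0)), 1: int(np.sum(y == 1))},
        hyperparameters=dict(hyperparameters or {}),
        seed=seed,
        scaler=scaler,
        variant=variant,
        provenance={"oversample_ratio": oversample_ratio, "n_train": len(partner_train)},
    )


def save_bundle(clf: TrainedClassifier, directory) -> Path:
    """Persist a model bundle: parameters + training fingerprints + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(clf.model, directory / "model.joblib")
    np.save(directory / "training_fingerprints.npy", clf.training_fingerprints)
    meta = {
        "bundle_version": 1,
        "architecture": clf.architecture,
        "config_hash": clf.config_hash,
        "label_counts": {str(k): v for k, v in clf.label_counts.items()},
        "hyperparameters": clf.hyperparameters,
        "seed": clf.seed,
        "variant": clf.variant,
        "provenance": clf.provenance,
        "scaler": clf.scaler.to_dict() if clf.scaler is not None else None,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return directory


def load_bundle(directory) -> TrainedClassifier:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    return TrainedClassifier(
        architecture=meta["architecture"],
        model=joblib.load(directory / "model.joblib"),
        training_fingerprints=np.load(directory / "training_fingerprints.npy"),
        config_hash=meta["config_hash"],
        label_counts={int(k): v for k, v in meta["label_counts"].items()},
        hyperparameters=meta["hyperparameters"],
        seed=meta["seed"],
        scaler=ScalerState.from_dict(meta["scaler"]) if meta.get("scaler") else None,
        variant=meta.get("variant", ""),
        provenance=meta.get("provenance", {}),
    )
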