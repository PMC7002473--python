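"""Classifier families for feature-matrix models, with grid search.

Six scikit-learn classifier families are wrapped behind a small spec
vocabulary: extra trees (ET), random forest (RF), support vector machine
(SVM), k-nearest neighbours (KNN), logistic regression (LR) and a multi-layer
perceptron (MLP).  Hyperparameters use the short names common in the
sequence-classification literature (``ne`` = n_estimators, ``g`` = gamma,
``k`` = kernel, ``a`` = activation, ``HL`` = hidden layer sizes, ``s`` =
solver, ``al`` = algorithm, ``w`` = weights, ``m`` = max_iter, ``nn`` =
n_neighbors); each family accepts only its own whitelist.

Grid search scores candidate specs by mean AUROC over externally supplied
cross-validation folds — the homology-aware folds from :mod:`prrkit.partition`,
never random row splits — so model selection sees no test-fold information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

_ARTIFACT_VERSION = 1

#: Short hyperparameter name → scikit-learn estimator parameter.
ABBREVIATIONS = {
    "ne": "n_estimators",
    "C": "C",
    "g": "gamma",
    "k": "kernel",
    "al": "algorithm",
    "nn": "n_neighbors",
    "w": "weights",
    "a": "activation",
    "HL": "hidden_layer_sizes",
    "s": "solver",
    "m": "max_iter",
}

#: Allowed short names per algorithm.
WHITELIST = {
    "ET": {"ne"},
    "RF": {"ne"},
    "SVM": {"C", "g", "k"},
    "KNN": {"al", "nn", "w"},
    "LR": {"C", "m"},
    "MLP": {"a", "HL", "s", "m"},
}

#: Default search grids.  Every published operating point for this problem
#: (tree-ensemble sizes 60-100, SVM C in {2,5,10} with gamma {0.01,0.5} rbf,
#: LR C in {1,1000}, KNN ball_tree/distance with 6 or 20 neighbours, MLP
#: widths 14/19/70 with tanh or logistic and adam) is reachable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ET": {"ne": [60, 70, 80, 90, 100]},
    "RF": {"ne": [60, 70, 80, 90, 100]},
    "SVM": {"C": [2, 5, 10], "g": [0.01, 0.5], "k": ["rbf"]},
    "KNN": {"nn": [6, 20], "al": ["ball_tree"], "w": ["distance"]},
    "LR": {"C": [1, 1000]},
    "MLP": {"HL": [(14,), (19,), (70,)], "a": ["tanh", "logistic"], "s": ["adam"], "m": [200]},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm name, short-name hyperparameters, and the random seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in WHITELIST:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {sorted(WHITELIST)}"
            )
        bad = set(self.hyperparameters) - WHITELIST[self.algorithm]
        if bad:
            raise ValueError(
                f"{self.algorithm}: hyperparameter(s) {sorted(bad)} not in whitelist "
                f"{sorted(WHITELIST[self.algorithm])}"
            )


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator a spec describes."""
    params = {ABBREVIATIONS[k]: v for k, v in spec.hyperparameters.items()}
    if spec.algorithm == "ET":
        return ExtraTreesClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "RF":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "SVM":
        # probability=True fits a Platt-style sigmoid on internal training-fold
        # splits, giving calibrated positive-class probabilities
        return SVC(probability=True, random_state=spec.seed, **params)
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if spec.algorithm == "LR":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(**params)
    return MLPClassifier(random_state=spec.seed, **params)


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed to use it safely."""

    spec: ModelSpec
    estimator: object
    schema: str  # feature schema tag, e.g. "AAC20"
    n_features: int
    fingerprint: str  # hash of the training matrix and labels

    def _check(self, X: np.ndarray, schema: str | None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if schema is not None and schema != self.schema:
            raise ValueError(f"schema mismatch: model {self.schema}, data {schema}")
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix must have {self.n_features} columns "
                f"(schema {self.schema}), got {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray, schema: str | None = None) -> np.ndarray:
        """Positive-class probabilities in [0, 1], one per row."""
        X = self._check(X, schema)
        proba = self.estimator.predict_proba(X)
        positive_col = list(self.estimator.classes_).index(1)
        return proba[:, positive_col]

    def predict(self, X: np.ndarray, threshold: float = 0.5,
                schema: str | None = None) -> np.ndarray:
        return (self.predict_proba(X, schema) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _ARTIFACT_VERSION,
                "spec": self.spec,
                "schema": self.schema,
                "n_features": self.n_features,
                "fingerprint": self.fingerprint,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _ARTIFACT_VERSION:
            raise ValueError(f"unsupported model artifact version in {path}")
        return cls(
            spec=payload["spec"],
            estimator=payload["estimator"],
            schema=payload["schema"],
            n_features=payload["n_features"],
            fingerprint=payload["fingerprint"],
        )


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are not aligned")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training rows")
    return X, y


def train_classifier(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, schema: str = "unspecified"
) -> TrainedModel:
    """Fit one classifier on a feature matrix; deterministic given the seed."""
    X, y = _validate_xy(X, y)
    estimator = build_estimator(spec)
    estimator.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        schema=schema,
        n_features=X.shape[1],
        fingerprint=joblib.hash((X, y)),
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    grid: Mapping[str, Sequence] | None,
    folds: Sequence[tuple[Sequence[int], Sequence[int]]],
    seed: int = 42,
    scoring: str = "roc_auc",
) -> ModelSpec:
    """Pick the spec maximizing mean fold AUROC over the given folds.

    ``folds`` are (train_indices, test_indices) pairs into the rows of X —
    produced by the homology-aware splitter, so candidate comparison never
    sees leaked homologs.  Ties go to the earlier grid point (deterministic).
    Selection by MCC instead is available through ``scoring="matthews_corrcoef"``.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    bad = set(grid) - WHITELIST[algorithm]
    if bad:
        raise ValueError(f"{algorithm}: grid key(s) {sorted(bad)} not in whitelist")
    X, y = _validate_xy(X, y)
    base = build_estimator(ModelSpec(algorithm, {}, seed))
    param_grid = {ABBREVIATIONS[k]: list(v) for k, v in grid.items()}
    cv = [(np.asarray(tr, dtype=int), np.asarray(te, dtype=int)) for tr, te in folds]
    search = GridSearchCV(base, param_grid, scoring=scoring, cv=cv, refit=False)
    search.fit(X, y)
    inverse = {v: k for k, v in ABBREVIATIONS.items()}
    chosen = {inverse[name]: value for name, value in search.best_params_.items()}
    return ModelSpec(algorithm, chosen, seed)
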