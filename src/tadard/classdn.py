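"""ClassDn: imbalanced-data classifiers for variant inheritance class.

Rare inherited variants outnumber de novo variants roughly thirtyfold, so
plain classifiers collapse onto the majority class.  Two resampling
ensembles are provided, both built on shallow decision trees:

* **RUSBoost** — AdaBoost-style boosting in which every weak learner is fit
  on a class-balanced random undersample of the majority class, weighted by
  the current boosting distribution.
* **Underbagging** — bootstrap aggregation in which every member sees a
  bootstrap of the minority class plus an equal-size random undersample of
  the majority class.

Both expose a de novo *score* in [0, 1] per variant (weighted mean of
member class-1 probabilities).  Thresholding the score at ``c`` classifies
a variant as "likely de novo" when the score strictly exceeds ``c``;
sensitivity ``w1 = P(X=1 | I=1)`` and specificity ``w2 = P(X=0 | I=0)``
then summarise the classifier for the downstream Random Draw model.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .exceptions import SchemaError
from .synthetic_data import COVARIATES

logger = logging.getLogger(__name__)

_MODEL_FORMAT_VERSION = 1

#: Pseudo-count added to allele frequency before the log transform; allele
#: frequencies span several orders of magnitude and contain exact zeros.
AF_PSEUDOCOUNT = 1e-9

DEFAULT_HYPERPARAMS = {
    "rusboost": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.5},
    "underbagging": {"n_estimators": 100, "max_depth": 3},
}


def _balanced_undersample(y: np.ndarray, rng: np.random.Generator,
                          bootstrap_minority: bool = False) -> np.ndarray:
    """Indices of a 1:1 subsample: minority class + undersampled majority."""
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)
    if bootstrap_minority:
        idx_min = rng.choice(idx_min, size=idx_min.size, replace=True)
    take_maj = rng.choice(idx_maj, size=idx_min.size, replace=False)
    return np.concatenate([idx_min, take_maj])


class _RUSBoost:
    """Boosting with random undersampling; binary labels in {0, 1}."""

    def __init__(self, n_estimators=100, max_depth=3, learning_rate=0.5,
                 random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        rng = np.random.default_rng(self.random_state)
        n = y.size
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        self.subsample_class_counts_ = []  # instrumentation: (n0, n1) per member
        eps = 1.0 / (2 * n)
        for _ in range(self.n_estimators):
            idx = _balanced_undersample(y, rng)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx], sample_weight=w[idx])
            pred = tree.predict(X)
            err = float(w[pred != y].sum())
            if err >= 0.5:
                # unhelpful member: drop it and re-draw a subsample
                continue
            err = max(err, eps)
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            counts = np.bincount(y[idx], minlength=2)
            self.subsample_class_counts_.append((int(counts[0]), int(counts[1])))
            w = w * np.exp(alpha * (pred != y))
            w /= w.sum()
        if not self.estimators_:
            # no member beat chance (e.g. pure-noise labels): fall back to a
            # single unweighted balanced tree so scores are still defined
            idx = _balanced_undersample(y, rng)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X[idx], y[idx])
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
            counts = np.bincount(y[idx], minlength=2)
            self.subsample_class_counts_ = [(int(counts[0]), int(counts[1]))]
        return self

    def score_samples(self, X) -> np.ndarray:
        alphas = np.asarray(self.alphas_)
        probas = np.stack([_proba_pos(t, X) for t in self.estimators_])
        return alphas @ probas / alphas.sum()


class _UnderBagging:
    """Bagging over balanced undersamples; binary labels in {0, 1}."""

    def __init__(self, n_estimators=100, max_depth=3, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        self.subsample_class_counts_ = []
        for _ in range(self.n_estimators):
            idx = _balanced_undersample(y, rng, bootstrap_minority=True)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X[idx], y[idx])
            self.estimators_.append(tree)
            counts = np.bincount(y[idx], minlength=2)
            self.subsample_class_counts_.append((int(counts[0]), int(counts[1])))
        return self

    def score_samples(self, X) -> np.ndarray:
        return np.mean([_proba_pos(t, X) for t in self.estimators_], axis=0)


def _proba_pos(tree, X) -> np.ndarray:
    proba = tree.predict_proba(X)
    if 1 in tree.classes_:
        return proba[:, list(tree.classes_).index(1)]
    return np.zeros(X.shape[0])


@dataclass
class ClassDnModel:
    """A fitted inheritance-class scorer with its frozen feature order."""

    algorithm: str
    estimator: object
    feature_order: tuple = COVARIATES
    rng_seed: int = 0
    n_dropped_rows: int = 0


def design_matrix(table: pd.DataFrame,
                  feature_order=COVARIATES) -> np.ndarray:
    """Feature matrix in the model's column order; AF is log-transformed."""
    missing = [c for c in feature_order if c not in table.columns]
    if missing:
        raise SchemaError(f"variant table is missing column(s): {missing}")
    X = table.loc[:, list(feature_order)].to_numpy(dtype=float).copy()
    af_col = list(feature_order).index("AF")
    X[:, af_col] = np.log10(X[:, af_col] + AF_PSEUDOCOUNT)
    return X


def train_classdn(training: pd.DataFrame, algorithm: str = "rusboost",
                  hyperparams: dict | None = None,
                  rng_seed: int = 0) -> ClassDnModel:
    """Fit ClassDn on a labeled variant table.

    Rows with any missing covariate or label are dropped (count logged).
    Raises if only one inheritance class is present — an imbalance-aware
    ensemble still needs examples of both classes.
    """
    if algorithm not in DEFAULT_HYPERPARAMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if "label" not in training.columns:
        raise SchemaError("training table has no 'label' column")
    params = dict(DEFAULT_HYPERPARAMS[algorithm])
    params.update(hyperparams or {})
    needed = list(COVARIATES) + ["label"]
    missing = [c for c in needed if c not in training.columns]
    if missing:
        raise SchemaError(f"training table is missing column(s): {missing}")
    complete = training[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("train_classdn: dropped %d row(s) with missing values",
                    n_dropped)
    kept = training.loc[complete]
    y = kept["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single inheritance class; "
                         "cannot fit a classifier")
    X = design_matrix(kept)
    cls = _RUSBoost if algorithm == "rusboost" else _UnderBagging
    est = cls(random_state=rng_seed, **params).fit(X, y)
    return ClassDnModel(algorithm=algorithm, estimator=est,
                        feature_order=COVARIATES, rng_seed=rng_seed,
                        n_dropped_rows=n_dropped)


def score_variants(model: ClassDnModel, table: pd.DataFrame) -> np.ndarray:
    """De novo score in [0, 1] per row, order-preserving with the input."""
    X = design_matrix(table, model.feature_order)
    if np.isnan(X).any():
        raise SchemaError("variant table contains missing covariate values")
    if X.shape[0] == 0:
        return np.empty(0)
    scores = model.estimator.score_samples(X)
    return np.clip(scores, 0.0, 1.0)


def classify_at_threshold(scores, c: float) -> np.ndarray:
    """Predicted class X: 1 iff the score strictly exceeds the threshold."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"threshold {c} outside [0, 1]")
    return (np.asarray(scores) > c).astype(int)


def estimate_performance(labels, predicted) -> tuple[float, float]:
    """(w1, w2): sensitivity and specificity of predictions vs true labels."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    n_dn = int((labels == 1).sum())
    n_inh = int((labels == 0).sum())
    if n_dn == 0 or n_inh == 0:
        raise ValueError("both inheritance classes must be present to "
                         "estimate sensitivity and specificity")
    w1 = float((predicted[labels == 1] == 1).mean())
    w2 = float((predicted[labels == 0] == 0).mean())
    return w1, w2


def performance_curve(labels, scores, threshold_grid) -> pd.DataFrame:
    """Sensitivity/specificity at each threshold of a sorted grid."""
    grid = np.asarray(threshold_grid, dtype=float)
    if grid.size and (np.any(np.diff(grid) < 0) or grid.min() < 0 or grid.max() > 1):
        raise ValueError("threshold grid must be sorted within [0, 1]")
    rows = []
    for c in grid:
        w1, w2 = estimate_performance(labels, classify_at_threshold(scores, c))
        rows.append((c, w1, w2))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def save_model(model: ClassDnModel, path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "feature_order": tuple(model.feature_order),
        "rng_seed": model.rng_seed,
        "n_dropped_rows": model.n_dropped_rows,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> ClassDnModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return ClassDnModel(algorithm=payload["algorithm"],
                        estimator=payload["estimator"],
                        feature_order=payload["feature_order"],
                        rng_seed=payload["rng_seed"],
                        n_dropped_rows=payload["n_dropped_rows"])
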