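"""Supervised comparison protocol.

The feature matrix is split 75/25 (stratified random sampling), model
quality is estimated on the training portion by repeated stratified
10-fold cross-validation (10 repetitions), and the model refitted on the
full training portion is scored once on the held-out 25%.  Four classifier
families are compared: linear discriminant analysis (shared-covariance
Gaussian discriminant), quadratic discriminant analysis (per-class
covariance, lightly ridge-regularized), k-nearest neighbours (Euclidean
metric, majority vote, ties resolved by the single nearest neighbour), and
random forest (500 trees, ``mtry`` candidate features per split).

Standardization (centring and scaling) is fitted inside every CV-training
portion and on the training split only, so validation folds and test rows
never leak into the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import preprocessing, windowing
from .synthetic import CLASS_LABELS, Dataset
from .windowing import FeatureMatrix

MODEL_FAMILIES: tuple[str, ...] = ("LDA", "QDA", "kNN", "RF")

QDA_RIDGE = 1e-6  # covariance regularization against near-singular folds


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration.

    ``k`` (neighbours) applies to kNN; ``mtry`` (candidate features per
    split) and ``n_trees`` apply to RF.
    """

    family: str
    k: int = 5
    mtry: int = 6
    n_trees: int = 500

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class NearestTieBreakKNN(BaseEstimator, ClassifierMixin):
    """k-NN with Euclidean metric and deterministic tie handling.

    Majority vote among the k nearest training points; a tied vote is
    resolved by the class of the single nearest neighbour.  Equal-distance
    neighbours are ordered by lowest training-sample index.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, self._y_idx = np.unique(y, return_inverse=True)
        self._nn = NearestNeighbors(n_neighbors=min(self.n_neighbors, X.shape[0]))
        self._nn.fit(X)
        return self

    def predict(self, X):
        _, neigh = self._nn.kneighbors(np.asarray(X, dtype=float))
        votes = self._y_idx[neigh]  # (n_queries, k)
        preds = np.empty(votes.shape[0], dtype=int)
        n_classes = self.classes_.shape[0]
        for i, row in enumerate(votes):
            counts = np.bincount(row, minlength=n_classes)
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            preds[i] = winners[0] if winners.size == 1 else row[0]
        return self.classes_[preds]


@dataclass(frozen=True)
class TrainTestSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_train_test(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> TrainTestSplit:
    """Stratified random train/test partition.

    Per class, round(train_fraction * n_class) samples go to training and
    the remainder to testing; the index sets are disjoint and reproducible
    by seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if isinstance(features, FeatureMatrix):
        labels = features.labels if labels is None else np.asarray(labels)
    elif labels is None:
        raise ValueError("labels are required with a bare value matrix")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return TrainTestSplit(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
    )


def build_estimator(spec: ModelSpec, seed: int = 0) -> Pipeline:
    """Standardization + classifier pipeline for one model spec."""
    if spec.family == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif spec.family == "QDA":
        # rank tolerance below the ridge so the regularized covariance is
        # always accepted as full rank
        clf = QuadraticDiscriminantAnalysis(reg_param=QDA_RIDGE, tol=QDA_RIDGE / 100)
    elif spec.family == "kNN":
        clf = NearestTieBreakKNN(n_neighbors=spec.k)
    else:  # RF
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=spec.mtry,
            random_state=int(seed) % (2**31),
        )
    return Pipeline([("standardize", StandardScaler()), ("model", clf)])


def repeated_cv(
    model: ModelSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified k-fold CV accuracy on the training portion.

    Returns the mean and sample sd of the fold-level accuracies, in
    percent.  Standardization is fitted on each CV-training portion only.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()} samples) cannot fill {folds} folds"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=int(seed) % (2**31)
    )
    accs = []
    for fold_train, fold_val in cv.split(X, y):
        est = build_estimator(model, seed=seed)
        est.fit(X[fold_train], y[fold_train])
        accs.append(float(np.mean(est.predict(X[fold_val]) == y[fold_val])))
    accs = np.asarray(accs)
    return float(accs.mean() * 100.0), float(accs.std(ddof=1) * 100.0)


def fit_predict(
    model: ModelSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit on the training split and predict labels for the test split."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if np.unique(y).size < len(CLASS_LABELS):
        raise ValueError("training split must contain all three classes")
    est = build_estimator(model, seed=seed)
    est.fit(X, y)
    return est.predict(np.asarray(test_features, dtype=float))


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def model_comparison(
    dataset: Dataset,
    window_counts,
    statistics=windowing.STATISTICS,
    model_specs: tuple[ModelSpec, ...] | None = None,
    seed: int = 0,
    train_fraction: float = 0.75,
    folds: int = 10,
    repeats: int = 10,
    mode: str = "slice_stats",
) -> pd.DataFrame:
    """Full (family x statistic x window) accuracy and confusion report.

    The 75/25 partition is drawn once from the labels and shared across
    every configuration, mirroring a single database split.  For each
    configuration, features are extracted, repeated CV is run on the
    training rows, the model is refitted on the full training split, and
    testing accuracy plus the 3x3 confusion matrix are reported.
    Accuracies are percentages.
    """
    window_counts = list(window_counts)
    statistics = list(statistics)
    if not window_counts or not statistics:
        raise ValueError("window_counts and statistics must be non-empty")
    if model_specs is None:
        model_specs = tuple(ModelSpec(family=f) for f in MODEL_FAMILIES)

    corrected = preprocessing.baseline_correct_dataset(dataset)
    split = split_train_test(None, labels=corrected.labels,
                             train_fraction=train_fraction,
                             seed=_derived_seed(seed, 0))
    rows = []
    for wi, w in enumerate(window_counts):
        scheme = windowing.make_window_scheme(w)
        for si, stat in enumerate(statistics):
            feats = windowing.extract_features(corrected, scheme, stat, mode=mode)
            X_train = feats.values[split.train_indices]
            y_train = feats.labels[split.train_indices]
            X_test = feats.values[split.test_indices]
            y_test = feats.labels[split.test_indices]
            for mi, spec in enumerate(model_specs):
                run_seed = _derived_seed(seed, 1 + wi, si, mi)
                val_mean, val_sd = repeated_cv(
                    spec, X_train, y_train, folds=folds, repeats=repeats, seed=run_seed
                )
                preds = fit_predict(spec, X_train, y_train, X_test, seed=run_seed)
                acc = float(np.mean(preds == y_test) * 100.0)
                cm = confusion_matrix(y_test, preds, labels=list(CLASS_LABELS))
                row = {
                    "family": spec.family,
                    "statistic": stat,
                    "window_count": w,
                    "validation_accuracy_mean": val_mean,
                    "validation_accuracy_sd": val_sd,
                    "testing_accuracy": acc,
                }
                for i, true_lab in enumerate(CLASS_LABELS):
                    for j, pred_lab in enumerate(CLASS_LABELS):
                        row[f"n_{true_lab}_as_{pred_lab}"] = int(cm[i, j])
                rows.append(row)
    return pd.DataFrame(rows)


def render_report_markdown(report: pd.DataFrame) -> str:
    """Render a model-comparison report as a compact markdown table.

    One block per window count; rows are model families, columns pair
    validation / testing accuracy per statistic, formatted to one decimal
    place.
    """
    lines = []
    for w in sorted(report["window_count"].unique()):
        sub = report[report["window_count"] == w]
        stats = list(dict.fromkeys(sub["statistic"]))
        lines.append(f"### {int(w)} window(s)\n")
        header = "| Model | " + " | ".join(
            f"{s} val (%) | {s} test (%)" for s in stats
        ) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (2 * len(stats) + 1))
        for fam in list(dict.fromkeys(sub["family"])):
            cells = [fam]
            for s in stats:
                r = sub[(sub["family"] == fam) & (sub["statistic"] == s)].iloc[0]
                cells.append(f"{r['validation_accuracy_mean']:.1f}")
                cells.append(f"{r['testing_accuracy']:.1f}")
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
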