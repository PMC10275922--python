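"""Unsupervised chemometrics: standardization, PCA, centroid distances.

PCA is computed by singular-value decomposition of the column-centred
matrix; each score PC_i is the projection sum_j a_ij V_j of the
(standardized) features onto an orthonormal loading vector.  Component
signs are fixed by forcing the largest-magnitude loading of each component
positive, so score plots do not flip between runs.

Cluster separation is quantified by the Euclidean distance between class
centroids (per-class feature means) in standardized feature space, or
optionally in the subspace of the first principal-component scores.  The
pork vs non-pork distance uses the pooled beef+chicken centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import preprocessing, windowing
from .synthetic import CLASS_LABELS, Dataset
from .windowing import FeatureMatrix

logger = logging.getLogger(__name__)

DISTANCE_PAIRS: tuple[str, ...] = (
    "beef-chicken", "beef-pork", "chicken-pork", "pork-nonpork"
)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column centre and scale fitted on a training matrix."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale


def standardize(
    features: FeatureMatrix,
) -> tuple[FeatureMatrix, StandardizationParams]:
    """Centre each column to mean 0 and scale to sample sd 1.

    Returns the transformed matrix and the fitted parameters, so held-out
    rows can be transformed with training-set statistics.  Zero-variance
    columns are scaled by 1 (centred only) with a logged warning.
    """
    X = features.values
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    degenerate = ~(scale > 0)
    if degenerate.any():
        bad = [features.feature_names[j] for j in np.flatnonzero(degenerate)]
        logger.warning("zero-variance column(s) scaled by 1: %s", ", ".join(bad))
        scale = np.where(degenerate, 1.0, scale)
    params = StandardizationParams(center=center, scale=scale)
    return (
        FeatureMatrix(
            values=params.transform(X),
            feature_names=features.feature_names,
            labels=features.labels,
            sample_ids=features.sample_ids,
        ),
        params,
    )


@dataclass(frozen=True)
class PCAResult:
    """Loadings (p x k), scores (n x k) and explained-variance ratios."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(features: FeatureMatrix | np.ndarray, k: int | None = None) -> PCAResult:
    """Principal components of a (standardized) feature matrix.

    The input is centred defensively and decomposed by SVD; ``k`` defaults
    to the matrix rank bound min(n - 1, p).  Requesting components beyond
    the numerical rank is rejected.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if k is None:
        k = min(n - 1, p, rank)
    if k > min(n - 1, p) or k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank bound (rank={rank})")
    # sign convention: largest-magnitude loading of each component positive
    for j in range(k):
        jmax = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, jmax] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total_var = float(np.sum(s**2))
    ratios = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(
        loadings=Vt[:k].T.copy(),
        scores=(U[:, :k] * s[:k]).copy(),
        explained_variance_ratio=ratios.copy(),
    )


def euclidean_distance(u, v) -> float:
    """d = sqrt(sum_j (u_j - v_j)^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def centroid_distances(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    space: str = "features",
    n_components: int = 2,
) -> pd.DataFrame:
    """Pairwise Euclidean distances between class centroids.

    Computed on the given (standardized) features by default, or on the
    first ``n_components`` PC scores with ``space="pc"``.  The
    pork-nonpork row uses the pooled beef+chicken centroid (the mean over
    all non-pork samples).
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels if labels is None else np.asarray(labels)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a bare value matrix")
        labels = np.asarray(labels)
    if space == "pc":
        X = pca(X, k=n_components).scores
    elif space != "features":
        raise ValueError(f"unknown space {space!r}; expected 'features' or 'pc'")

    centroids = {}
    for label in CLASS_LABELS:
        mask = labels == label
        if not mask.any():
            raise ValueError(f"class {label!r} has no samples")
        centroids[label] = X[mask].mean(axis=0)
    nonpork = X[labels != "pork"].mean(axis=0)

    rows = []
    for a, b in combinations(("beef", "chicken", "pork"), 2):
        rows.append({"pair": f"{a}-{b}", "distance": euclidean_distance(centroids[a], centroids[b])})
    rows.append({"pair": "pork-nonpork", "distance": euclidean_distance(centroids["pork"], nonpork)})
    return pd.DataFrame(rows)


def distance_vs_windows(
    dataset: Dataset,
    window_range,
    statistics=windowing.STATISTICS,
    mode: str = "slice_stats",
    space: str = "features",
) -> pd.DataFrame:
    """Centroid-distance table over (window count x statistic x pair).

    The dataset is baseline-corrected (idempotent) and, for each window
    count and statistic, features are extracted, standardized, and the
    four pairwise centroid distances computed.  Deterministic given the
    dataset.
    """
    window_range = list(window_range)
    if not window_range:
        raise ValueError("window_range must be non-empty")
    corrected = preprocessing.baseline_correct_dataset(dataset)
    rows = []
    for w in window_range:
        scheme = windowing.make_window_scheme(w)
        for stat in statistics:
            feats = windowing.extract_features(corrected, scheme, stat, mode=mode)
            standardized, _ = standardize(feats)
            table = centroid_distances(standardized, space=space)
            for _, rec in table.iterrows():
                rows.append(
                    {
                        "window_count": w,
                        "statistic": stat,
                        "pair": rec["pair"],
                        "distance": rec["distance"],
                    }
                )
    return pd.DataFrame(rows)
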