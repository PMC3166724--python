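"""Floating feature selection (SFFS-SFBS) and PCA rotation/reduction.

The floating search is driven by a same-class compactness criterion (the
negative mean Euclidean distance between feature vectors of the same class,
on standardized features); the best subset recorded at each size is then
arbitrated by k-NN cross-validated accuracy, and the minimal-size subset
maximizing that accuracy is selected. PCA is applied afterwards for
rotation and, optionally, dimensionality reduction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "SelectionResult",
    "PCAModel",
    "sffs_select",
    "knn_cv_accuracy",
    "pca_fit",
    "pca_transform",
    "pca_inverse_transform",
]


@dataclass
class SelectionResult:
    """Outcome of the floating search."""

    selected: tuple[int, ...]
    criterion_trace: dict[int, float]
    accuracy_trace: dict[int, float]
    knn_accuracy: float
    subsets_by_size: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "criterion_trace": {str(k): v for k, v in self.criterion_trace.items()},
            "accuracy_trace": {str(k): v for k, v in self.accuracy_trace.items()},
            "knn_accuracy": self.knn_accuracy,
            "subsets_by_size": {
                str(k): list(v) for k, v in self.subsets_by_size.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _compactness(Xs: np.ndarray, y: np.ndarray, subset: tuple[int, ...]) -> float:
    """Negative mean same-class pairwise Euclidean distance (larger = better)."""
    total, count = 0.0, 0
    sub = Xs[:, list(subset)]
    for cls in np.unique(y):
        d = pdist(sub[y == cls])
        total += d.sum()
        count += d.size
    return -total / count


def knn_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    k: int = 5,
    folds: int = 10,
    rng_seed: int = 0,
) -> float:
    """Stratified cross-validated k-NN accuracy on a feature subset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    folds = max(2, min(folds, int(counts.min())))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    clf = KNeighborsClassifier(n_neighbors=k)
    scores = cross_val_score(clf, X[:, list(subset)], y, cv=cv)
    return float(scores.mean())


def sffs_select(
    X,
    y,
    k: int = 5,
    folds: int = 10,
    rng_seed: int = 0,
) -> SelectionResult:
    """Sequential forward-backward floating selection (Pudil-style).

    Forward steps add the feature maximizing same-class compactness;
    conditional backward steps remove a feature whenever that improves on
    the best subset previously recorded at the smaller size. The search
    runs until every feature has entered the candidate set (the trace then
    covers sizes 1..d), after which the minimal-size subset maximizing the
    k-NN cross-validated accuracy is returned. Ties in accuracy prefer the
    smaller size, then lexicographic index order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes for selection")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    if not 1 <= k < counts.min() * (len(classes) > 0):
        k = max(1, min(k, int(counts.min()) - 1))
    Xs = _standardize(X)

    best_J: dict[int, float] = {}
    best_subset: dict[int, tuple[int, ...]] = {}

    def record(subset: tuple[int, ...]) -> None:
        size = len(subset)
        val = _compactness(Xs, y, subset)
        if size not in best_J or val > best_J[size] or (
            val == best_J[size] and subset < best_subset[size]
        ):
            best_J[size] = val
            best_subset[size] = subset

    current: list[int] = []
    while len(current) < d:
        # conditional inclusion: best feature not in the set
        candidates = [f for f in range(d) if f not in current]
        vals = [
            _compactness(Xs, y, tuple(sorted(current + [f]))) for f in candidates
        ]
        best = int(np.argmax(vals))  # first max -> lowest feature index
        current.append(candidates[best])
        record(tuple(sorted(current)))
        # conditional exclusion: float back while it beats the stored best
        while len(current) > 2:
            sub_vals = [
                _compactness(Xs, y, tuple(sorted(set(current) - {f})))
                for f in current
            ]
            worst = int(np.argmax(sub_vals))
            reduced = tuple(sorted(set(current) - {current[worst]}))
            if sub_vals[worst] > best_J.get(len(reduced), -np.inf):
                current = list(reduced)
                record(reduced)
            else:
                break

    accuracy_trace = {
        size: knn_cv_accuracy(X, y, subset, k=k, folds=folds, rng_seed=rng_seed)
        for size, subset in sorted(best_subset.items())
    }
    best_acc = max(accuracy_trace.values())
    chosen_size = min(s for s, a in accuracy_trace.items() if a == best_acc)
    return SelectionResult(
        selected=best_subset[chosen_size],
        criterion_trace=dict(sorted(best_J.items())),
        accuracy_trace=accuracy_trace,
        knn_accuracy=best_acc,
        subsets_by_size=dict(sorted(best_subset.items())),
    )


@dataclass
class PCAModel:
    """PCA of column-standardized features.

    rotation columns are the orthonormal principal axes in order of
    non-increasing variance fraction.
    """

    mean: np.ndarray
    scale: np.ndarray
    rotation: np.ndarray
    variance_fractions: np.ndarray
    n_keep: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "rotation": self.rotation.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_keep": self.n_keep,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            np.array(d["mean"]),
            np.array(d["scale"]),
            np.array(d["rotation"]),
            np.array(d["variance_fractions"]),
            int(d["n_keep"]),
        )


def pca_fit(X, variance_target: float | None = None, n_keep: int | None = None) -> PCAModel:
    """Eigendecomposition of the standardized sample covariance.

    ``n_keep`` is the smallest component count whose cumulative variance
    fraction reaches ``variance_target``, or the explicit value; with
    neither given, all components are kept (pure rotation).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two samples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("zero-variance feature column(s); PCA undefined")
    Z = (X - mean) / scale
    cov = Z.T @ Z / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    rotation = eigvecs[:, order]
    fractions = eigvals / eigvals.sum()
    d = X.shape[1]
    if n_keep is None:
        if variance_target is None:
            n_keep = d
        else:
            n_keep = int(np.searchsorted(np.cumsum(fractions), variance_target - 1e-12) + 1)
            n_keep = min(n_keep, d)
    if not 1 <= n_keep <= d:
        raise ValueError(f"n_keep must be in [1, {d}]")
    return PCAModel(mean, scale, rotation, fractions, n_keep)


def pca_transform(model: PCAModel, X) -> np.ndarray:
    """Project onto the first ``n_keep`` principal components."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[-1]} != model dimension {model.mean.shape[0]}"
        )
    Z = (X - model.mean) / model.scale
    return Z @ model.rotation[:, : model.n_keep]


def pca_inverse_transform(model: PCAModel, Z) -> np.ndarray:
    """Map component scores back to the original feature space."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[-1] != model.n_keep:
        raise ValueError("score dimension does not match n_keep")
    Xs = Z @ model.rotation[:, : model.n_keep].T
    return Xs * model.scale + model.mean
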