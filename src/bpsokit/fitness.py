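"""Wrapper fitness for feature subsets.

A subset is scored by stratified k-fold cross-validated classification
accuracy on the selected columns, minus a small parsimony penalty
``alpha * (selected / total)``.  Columns are z-scored with the training-fold
statistics of each fold (zero-variance columns pass through unscaled, as in
``StandardScaler``).

The nearest-neighbour path precomputes, per fold and per feature, the squared
differences between every test and training sample.  A subset's distance
matrix is then just a sum of slices, which makes the ~10^5 evaluations of a
swarm run affordable; results are memoized by mask.  Tests verify this path
against a ``StandardScaler`` + ``KNeighborsClassifier`` pipeline scored with
``cross_val_score``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

CLASSIFIERS = ("nearest_neighbor", "linear_discriminant")


@dataclass
class FitnessSpec:
    """How subsets are scored: classifier, CV folds, parsimony penalty, seed."""

    classifier: str = "nearest_neighbor"
    cv_folds: int = 5
    parsimony_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.parsimony_alpha < 0:
            raise ValueError("parsimony_alpha must be >= 0")


def repair_empty_mask(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero subset repair: activate one uniformly random feature."""
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(bits.shape[0])] = 1
    return bits


class SubsetFitness:
    """Callable scoring bit masks over the columns of a fixed table.

    Deterministic given ``spec.seed`` (which only shuffles the fold
    assignment).  ``n_calls`` counts invocations, memoized or not.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: FitnessSpec | None = None):
        spec = spec or FitnessSpec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("labels must contain exactly two classes")
        if spec.cv_folds > counts.min():
            raise ValueError("cv_folds exceeds the size of the smaller class")
        self.spec = spec
        self.n_features = X.shape[1]
        self.n_calls = 0
        self._cache: dict = {}
        skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
        self._folds = list(skf.split(X, y))
        if spec.classifier == "nearest_neighbor":
            self._tensors = []  # per fold: (sqdiff (d, n_test, n_train), y_train, y_test)
            for train, test in self._folds:
                mu = X[train].mean(axis=0)
                sd = X[train].std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                zt = (X[train] - mu) / sd
                zs = (X[test] - mu) / sd
                sq = (zs[:, None, :] - zt[None, :, :]) ** 2  # (n_test, n_train, d)
                self._tensors.append((np.ascontiguousarray(sq.transpose(2, 0, 1)), y[train], y[test]))
        else:
            self._X, self._y = X, y

    def accuracy(self, mask: np.ndarray) -> float:
        """Mean over folds of the classifier's test-fold accuracy."""
        mask = np.asarray(mask).astype(bool)
        if mask.shape[0] != self.n_features:
            raise ValueError("mask length does not match the number of features")
        if mask.sum() == 0:
            raise ValueError("mask selects no features")
        if self.spec.classifier == "nearest_neighbor":
            idx = np.flatnonzero(mask)
            accs = []
            for sq, ytr, yte in self._tensors:
                dist = sq[idx].sum(axis=0)
                pred = ytr[np.argmin(dist, axis=1)]
                accs.append(float(np.mean(pred == yte)))
            return float(np.mean(accs))
        # linear discriminant path (slow; used for small problems only)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        Xm = self._X[:, mask]
        accs = []
        for train, test in self._folds:
            clf = make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
            clf.fit(Xm[train], self._y[train])
            accs.append(float(clf.score(Xm[test], self._y[test])))
        return float(np.mean(accs))

    def __call__(self, mask: np.ndarray) -> float:
        self.n_calls += 1
        mask = np.asarray(mask).astype(bool)
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is None:
            k = int(mask.sum())
            hit = self.accuracy(mask) - self.spec.parsimony_alpha * k / self.n_features
            self._cache[key] = hit
        return hit
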