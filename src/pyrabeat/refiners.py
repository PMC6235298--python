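"""Level-2 refiners: morphology-aware classifiers behind the dispatcher.

Beats routed to the N group are re-examined by a mixed ensemble of seven
classical classifiers (the *nRefiner*) that separates true normals from
ventricular ectopic, fusion and unknown beats; beats routed to the S group
go to a single support-vector machine (the *sRefiner*) trained without
rhythm features, because ventricular beats can be just as premature as
supraventricular ones and rhythm would mislead it.

The N group is dominated by normal beats, so every ensemble member trains
on a class-balanced resample of the training data; predictions are merged
by majority vote with ties broken in favor of the disease classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: Tie-break priority for the majority vote: disease classes first.
VOTE_PRIORITY = ("V", "F", "Q", "S", "N")


def _balanced_resample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced resample (uniform class proportions).

    Each class is drawn to the median class count: majority classes are
    undersampled without replacement, minority classes bootstrapped up.
    """
    classes, counts = np.unique(y, return_counts=True)
    target = max(1, int(np.median(counts)))
    idx = []
    for cls, cnt in zip(classes, counts):
        members = np.flatnonzero(y == cls)
        if cnt >= target:
            idx.append(rng.choice(members, size=target, replace=False))
        else:
            idx.append(rng.choice(members, size=target, replace=True))
    return np.concatenate(idx)


def _majority_vote(votes: np.ndarray) -> np.ndarray:
    """Per-column plurality over a (n_voters, n_samples) label array.

    Ties are resolved by the fixed priority V > F > Q > S > N, favoring
    sensitivity to disease beats.
    """
    out = np.empty(votes.shape[1], dtype=object)
    for j in range(votes.shape[1]):
        col = votes[:, j]
        classes, counts = np.unique(col, return_counts=True)
        winners = classes[counts == counts.max()]
        out[j] = min(winners, key=VOTE_PRIORITY.index)
    return out.astype(str)


class _RefinerBase(BaseEstimator, ClassifierMixin):
    """Shared plumbing: feature-width check and class-set validation."""

    allowed_classes: tuple[str, ...] = ()
    expected_n_features: int = 0

    def _validate(self, X, y=None, fitting=False):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.expected_n_features:
            raise ValueError(
                f"{type(self).__name__} expects {self.expected_n_features} "
                f"features, got {X.shape[1] if X.ndim == 2 else X.ndim}-d input"
            )
        if y is None:
            return X
        y = np.asarray(y, dtype=object).astype(str)
        bad = set(y) - set(self.allowed_classes)
        if bad:
            raise ValueError(
                f"labels {sorted(bad)} outside class set {self.allowed_classes}"
            )
        if fitting:
            present = [c for c in self.allowed_classes if c in set(y)]
            missing = set(self.allowed_classes) - set(present)
            if missing:
                logger.warning(
                    "%s: classes %s absent from training; removed from model",
                    type(self).__name__, sorted(missing),
                )
            self.classes_ = np.array(present)
        return X, y


class NRefiner(_RefinerBase):
    """Mixed ensemble classifying N-group beats into {N, V, F, Q}.

    Seven base learners — linear-kernel SVM, RBF SVM, decision tree,
    k-nearest-neighbors, logistic regression, perceptron and Gaussian
    naive Bayes — each fitted on its own class-balanced resample of the
    32-feature training beats (rhythm + shape statistics + wavelet
    coefficients), aggregated by majority vote.

    The seven learners and their hyperparameters are fixed defaults
    chosen for a reproducible baseline; all are standard off-the-shelf
    configurations (k = 5 neighbors, RBF gamma scaled to the data,
    minimum leaf of 5 for the tree).
    """

    allowed_classes = ("N", "V", "F", "Q")
    expected_n_features = 32

    def __init__(self, random_state: int | None = 0):
        self.random_state = random_state

    def _base_learners(self, seed: int):
        mk = lambda est: make_pipeline(StandardScaler(), est)  # noqa: E731
        return [
            mk(SVC(kernel="linear", random_state=seed)),
            mk(SVC(kernel="rbf", gamma="scale", random_state=seed)),
            mk(DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)),
            mk(KNeighborsClassifier(n_neighbors=5)),
            mk(LogisticRegression(max_iter=2000, random_state=seed)),
            mk(Perceptron(max_iter=2000, random_state=seed)),
            mk(GaussianNB()),
        ]

    def fit(self, X, y) -> "NRefiner":
        X, y = self._validate(X, y, fitting=True)
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        self.estimators_ = []
        for est in self._base_learners(seed):
            idx = _balanced_resample(y, rng)
            est = clone(est)
            self.estimators_.append(est.fit(X[idx], y[idx]))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = self._validate(X)
        votes = np.stack([est.predict(X) for est in self.estimators_])
        return _majority_vote(votes)


class SRefiner(_RefinerBase):
    """Support-vector machine classifying S-group beats into {S, V, F, Q}.

    Trains on the 30 morphology features only (shape statistics and
    wavelet coefficients, rhythm excluded) with standardized inputs.
    """

    allowed_classes = ("S", "V", "F", "Q")
    expected_n_features = 30

    def __init__(self, random_state: int | None = 0):
        self.random_state = random_state

    def fit(self, X, y) -> "SRefiner":
        X, y = self._validate(X, y, fitting=True)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.estimator_ = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", gamma="scale", class_weight="balanced",
                random_state=seed),
        ).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = self._validate(X)
        return np.asarray(self.estimator_.predict(X), dtype=object).astype(str)


def classify_level2(
    features: pd.DataFrame,
    level1: np.ndarray,
    nref: NRefiner,
    sref: SRefiner,
) -> np.ndarray:
    """Route beats through the refiner matching their level-1 group.

    ``features`` must carry the full 32-feature layout; the S-group view
    (rhythm columns dropped) is derived internally.  Outputs are merged
    back in the original beat order.
    """
    from pyrabeat.features import assemble_features

    level1 = np.asarray(level1, dtype=object).astype(str)
    if len(features) != len(level1):
        raise ValueError("features and level-1 labels must align")
    out = np.empty(len(level1), dtype=object)
    n_mask = level1 == "N"
    s_mask = level1 == "S"
    if not np.all(n_mask | s_mask):
        raise ValueError("level-1 labels must be 'N' or 'S'")
    if n_mask.any():
        out[n_mask] = nref.predict(assemble_features(features[n_mask], "nrefiner"))
    if s_mask.any():
        out[s_mask] = sref.predict(assemble_features(features[s_mask], "srefiner"))
    return out.astype(str)
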