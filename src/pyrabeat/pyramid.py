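"""The full two-level pyramid classifier.

Level 1 routes every beat into an N group or an S group using only
rhythm (the :class:`~pyrabeat.dispatcher.NSDispatcher`); level 2 refines
each group with a morphology-aware classifier
(:class:`~pyrabeat.refiners.NRefiner` / :class:`~pyrabeat.refiners.SRefiner`).
A beat can only end up labeled N if level 1 put it in the N group, and
only labeled S if level 1 put it in the S group; V, F and Q are reachable
from both groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from pyrabeat.dispatcher import NSDispatcher
from pyrabeat.features import (
    FEATURE_NAMES,
    assemble_features,
    extract_features,
    zscore_by_recording,
)
from pyrabeat.preprocess import preprocess_recording
from pyrabeat.refiners import NRefiner, SRefiner, classify_level2


def recordings_to_features(
    recordings, *, denoise: bool = True
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Run the cleaning + feature pipeline over a cohort of recordings.

    Returns ``(X, y, patients)``: the 32-column feature table, the AAMI
    labels, and the per-beat patient ids, ready for
    :class:`PyramidClassifier`.
    """
    frames, labels, pids = [], [], []
    for rec in recordings:
        segments = preprocess_recording(rec, denoise=denoise)
        feats = extract_features(segments)
        labels.extend(feats.pop("label"))
        feats = feats.drop(columns=["beat_index"])
        frames.append(feats)
        pids.extend([rec.patient_id] * len(feats))
    X = pd.concat(frames, ignore_index=True)
    return X, np.asarray(labels, dtype=object).astype(str), np.asarray(pids, dtype=object)


class PyramidClassifier(BaseEstimator, ClassifierMixin):
    """Two-level heartbeat classifier over the five AAMI classes.

    Training uses ground-truth groups: the N-refiner learns from all
    training beats labeled {N, V, F, Q} and the S-refiner from all beats
    labeled {S, V, F, Q}, so refiner quality is not coupled to dispatcher
    errors.  Rhythm features enter the dispatcher rules in seconds (the
    rules are scale-free ratios); all features are z-scored per recording
    before reaching the refiners, removing patient-level offset and gain.

    Parameters
    ----------
    step : float
        Dispatcher threshold-grid resolution.
    n_clusters : int
        Signature size for the EMD neighbor lookup.
    random_state : int
        Seed for the refiners' balanced resampling.

    Attributes
    ----------
    dispatcher_ : NSDispatcher
    nrefiner_ : NRefiner
    srefiner_ : SRefiner
    classes_ : ndarray of the five AAMI classes
    """

    def __init__(
        self,
        step: float = 0.05,
        n_clusters: int = 10,
        random_state: int = 0,
    ):
        self.step = step
        self.n_clusters = n_clusters
        self.random_state = random_state

    @staticmethod
    def _check_features(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(FEATURE_NAMES))
        missing = set(FEATURE_NAMES) - set(X.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        return X

    @staticmethod
    def _zscore_per_patient(X: pd.DataFrame, patients: np.ndarray) -> pd.DataFrame:
        parts = []
        for pid in pd.unique(patients):
            block = X.loc[patients == pid, list(FEATURE_NAMES)]
            parts.append(zscore_by_recording(block))
        return pd.concat(parts).loc[X.index]

    def fit(self, X, y, patients=None) -> "PyramidClassifier":
        """Fit dispatcher and both refiners on labeled training beats.

        Parameters
        ----------
        X : DataFrame with the 32 canonical feature columns
            Rhythm columns in seconds, morphology unscaled.
        y : array-like of AAMI labels {N, S, V, F, Q}.
        patients : array-like of per-beat patient ids (required).
        """
        X = self._check_features(X)
        y = np.asarray(y, dtype=object).astype(str)
        if patients is None:
            raise ValueError("PyramidClassifier.fit requires per-beat patient ids")
        patients = np.asarray(patients, dtype=object).astype(str)

        self.dispatcher_ = NSDispatcher(
            step=self.step, n_clusters=self.n_clusters
        ).fit(assemble_features(X, "dispatcher"), y, patients=patients)

        Xz = self._zscore_per_patient(X, patients)
        n_mask = np.isin(y, NRefiner.allowed_classes)
        s_mask = np.isin(y, SRefiner.allowed_classes)
        self.nrefiner_ = NRefiner(random_state=self.random_state).fit(
            assemble_features(Xz[n_mask], "nrefiner"), y[n_mask]
        )
        self.srefiner_ = SRefiner(random_state=self.random_state).fit(
            assemble_features(Xz[s_mask], "srefiner"), y[s_mask]
        )
        self.classes_ = np.array(["N", "S", "V", "F", "Q"])
        return self

    def predict_level1(self, X, patients=None) -> np.ndarray:
        """Level-1 N/S routing only."""
        check_is_fitted(self, "dispatcher_")
        X = self._check_features(X)
        return self.dispatcher_.predict(
            assemble_features(X, "dispatcher"), patients=patients
        )

    def predict(self, X, patients=None) -> np.ndarray:
        """Full two-level prediction into {N, S, V, F, Q}."""
        check_is_fitted(self, "dispatcher_")
        X = self._check_features(X)
        if patients is None:
            patients = np.zeros(len(X), dtype=object)
        patients = np.asarray(patients, dtype=object).astype(str)
        level1 = self.predict_level1(X, patients=patients)
        Xz = self._zscore_per_patient(X, patients)
        return classify_level2(Xz, level1, self.nrefiner_, self.srefiner_)
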