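"""Level-1 N/S dispatcher: per-patient RR-ratio rules with EMD transfer.

Supraventricular ectopic (S) beats share the QRS morphology of normal
beats but arrive early, so the dispatcher ignores morphology entirely and
decides N vs S from two scale-free rhythm ratios.  A beat is called S when
either rule fires:

* rule 1: ``(pre_rr - post_rr) / normal_pre_rr < t`` — a premature beat
  followed by a compensatory pause;
* rule 2: ``(pre_rr - normal_pre_rr) / normal_pre_rr < t`` — a premature
  beat relative to the patient's own normal rhythm;

where ``normal_pre_rr`` is the patient's typical pre-RR and ``t < 0`` is a
patient-specific threshold.  Thresholds are learned per training patient
by grid search and transferred to an unseen patient from the training
patient whose pre-RR distribution is nearest in earth mover's distance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from pyrabeat.emd import Signature, build_signature, earth_movers_distance
from pyrabeat.features import zscore_by_recording

logger = logging.getLogger(__name__)

#: Sentinel threshold meaning "this training patient had no S beats".
NO_S_SENTINEL = 0.0


def threshold_grid(step: float = 0.05) -> np.ndarray:
    """Candidate thresholds {-step, -2*step, ...} inside the open interval (-1, 0)."""
    n = int(round(1.0 / step)) - 1
    return -step * np.arange(1, n + 1)


def apply_rules(
    pre_rr: np.ndarray | float,
    post_rr: np.ndarray | float,
    normal_pre_rr: float,
    t: float,
) -> np.ndarray | str:
    """Apply the two premature-beat rules; returns 'S' where either fires.

    Scalar inputs return a scalar label; array inputs return an array of
    labels aligned with the beats.
    """
    if normal_pre_rr <= 0:
        raise ValueError("normal_pre_rr must be positive")
    pre = np.asarray(pre_rr, dtype=float)
    post = np.asarray(post_rr, dtype=float)
    rule1 = (pre - post) / normal_pre_rr < t
    rule2 = (pre - normal_pre_rr) / normal_pre_rr < t
    labels = np.where(rule1 | rule2, "S", "N")
    if labels.ndim == 0:
        return str(labels)
    return labels


def estimate_normal_prerr(pre_rrs: np.ndarray) -> float:
    """Estimate a patient's normal pre-RR, robust to frequent S beats.

    Outliers are flagged by Tukey fences (1.5 x IQR beyond the quartiles).
    With at most 10% outliers the recording is assumed dominated by normal
    beats and the plain median is returned; with more, the median may sit
    on ectopic beats, so the estimate is the mean of the outlier mean and
    the overall median.
    """
    x = np.asarray(pre_rrs, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot estimate normal pre-RR from no beats")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = x[(x < lo) | (x > hi)]
    if outliers.size / x.size > 0.1:
        return float(np.mean([outliers.mean(), np.median(x)]))
    return float(np.median(x))


def _sensitivity(cls: str, true: np.ndarray, pred: np.ndarray) -> float:
    mask = true == cls
    if not mask.any():
        return np.nan
    return float(np.mean(pred[mask] == cls))


class NSDispatcher(BaseEstimator, ClassifierMixin):
    """Rule-based N/S heartbeat classifier with per-patient thresholds.

    Parameters
    ----------
    step : float
        Grid resolution for the threshold search inside (-1, 0).
    n_clusters : int
        Maximum number of clusters in the pre-RR signatures used for the
        EMD neighbor lookup.
    fallback_t : float
        Threshold used when every training patient is S-free (degenerate
        table whose minimum is the sentinel 0).

    Attributes
    ----------
    thresholds_ : dict[str, float]
        Learned threshold per training patient; 0 marks an S-free patient.
    normal_pre_rr_ : dict[str, float]
        Median N-beat pre-RR per training patient, in seconds.
    signatures_ : dict[str, Signature]
        Z-scored pre-RR signatures for the neighbor lookup.
    classes_ : ndarray
        Always ``["N", "S"]``.
    """

    def __init__(
        self, step: float = 0.05, n_clusters: int = 10, fallback_t: float = -0.05
    ):
        self.step = step
        self.n_clusters = n_clusters
        self.fallback_t = fallback_t

    # ------------------------------------------------------------------
    def fit(self, X, y, patients=None) -> "NSDispatcher":
        """Learn one threshold per training patient by exhaustive search.

        Parameters
        ----------
        X : array-like of shape (n_beats, 2) or DataFrame
            Per-beat ``(pre_rr, post_rr)`` in seconds (DataFrame columns
            ``preRR``/``postRR`` are also accepted).
        y : array-like of str
            AAMI labels; beats outside {N, S} are ignored in training.
        patients : array-like of str
            Per-beat patient identifier (required: thresholds are
            patient-specific).
        """
        pre, post = self._split_columns(X)
        y = np.asarray(y, dtype=object).astype(str)
        if patients is None:
            raise ValueError("NSDispatcher.fit requires per-beat patient ids")
        patients = np.asarray(patients, dtype=object).astype(str)
        if not (len(pre) == len(y) == len(patients)):
            raise ValueError("X, y and patients must align")

        grid = threshold_grid(self.step)
        self.thresholds_ = {}
        self.normal_pre_rr_ = {}
        self.signatures_ = {}
        for pid in pd.unique(patients):
            sel = patients == pid
            p_pre, p_post, p_y = pre[sel], post[sel], y[sel]
            ns = np.isin(p_y, ["N", "S"])
            n_mask = p_y == "N"
            if not n_mask.any():
                raise ValueError(
                    f"patient {pid!r} has no N beats; normal pre-RR undefined"
                )
            normal_pre_rr = float(np.median(p_pre[n_mask]))
            self.normal_pre_rr_[pid] = normal_pre_rr
            self.signatures_[pid] = build_signature(
                zscore_by_recording(p_pre), self.n_clusters
            )
            if not (p_y == "S").any():
                self.thresholds_[pid] = NO_S_SENTINEL
                continue
            true_ns = p_y[ns]
            best_t, best_obj = None, -np.inf
            for t in grid:  # grid is ordered from least to most negative
                pred = apply_rules(p_pre[ns], p_post[ns], normal_pre_rr, t)
                obj = _sensitivity("N", true_ns, pred) + _sensitivity(
                    "S", true_ns, pred
                )
                if obj > best_obj:  # strict: ties keep the largest t
                    best_obj, best_t = obj, float(t)
            self.thresholds_[pid] = best_t
        self.classes_ = np.array(["N", "S"])
        return self

    # ------------------------------------------------------------------
    def get_neighbor(self, test_pre_rrs: np.ndarray) -> str:
        """Training patient whose pre-RR distribution is nearest in EMD."""
        check_is_fitted(self, "signatures_")
        sig = build_signature(
            zscore_by_recording(np.asarray(test_pre_rrs, dtype=float)),
            self.n_clusters,
        )
        best_pid, best_d = None, np.inf
        for pid, train_sig in self.signatures_.items():
            d = earth_movers_distance(sig, train_sig)
            if d < best_d:
                best_d, best_pid = d, pid
        return best_pid

    def threshold_for(self, test_pre_rrs: np.ndarray) -> tuple[str, float]:
        """Neighbor id and the effective threshold for a test patient.

        A neighbor holding the S-free sentinel (t = 0) is replaced by the
        most negative threshold in the table — a potential S beat should
        never be missed because the nearest training patient happened to
        have none.
        """
        neighbor = self.get_neighbor(test_pre_rrs)
        t = self.thresholds_[neighbor]
        if t == NO_S_SENTINEL:
            t = min(self.thresholds_.values())
            if t == NO_S_SENTINEL:
                logger.warning(
                    "all training thresholds are the S-free sentinel; "
                    "falling back to t = %g", self.fallback_t,
                )
                t = self.fallback_t
        return neighbor, float(t)

    def predict(self, X, patients=None) -> np.ndarray:
        """Label each beat N or S, processing each test patient separately.

        For every patient the normal pre-RR is estimated from that
        patient's own beats (Tukey-fence robust estimator) and the
        threshold is transferred from the nearest training patient.
        """
        check_is_fitted(self, "thresholds_")
        pre, post = self._split_columns(X)
        if patients is None:
            patients = np.zeros(len(pre), dtype=object)
        patients = np.asarray(patients, dtype=object).astype(str)
        out = np.empty(len(pre), dtype=object)
        for pid in pd.unique(patients):
            sel = patients == pid
            normal_pre_rr = estimate_normal_prerr(pre[sel])
            _, t = self.threshold_for(pre[sel])
            out[sel] = apply_rules(pre[sel], post[sel], normal_pre_rr, t)
        return out.astype(str)

    # ------------------------------------------------------------------
    @staticmethod
    def _split_columns(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            return (
                X["preRR"].to_numpy(dtype=float),
                X["postRR"].to_numpy(dtype=float),
            )
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be (n_beats, 2): pre-RR and post-RR")
        return arr[:, 0], arr[:, 1]

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the threshold table (thresholds, normal pre-RRs, signatures)."""
        check_is_fitted(self, "thresholds_")
        obj = {
            pid: {
                "t": self.thresholds_[pid],
                "normal_pre_rr": self.normal_pre_rr_[pid],
                "signature": np.column_stack(
                    [
                        self.signatures_[pid].representatives,
                        self.signatures_[pid].weights,
                    ]
                ).tolist(),
            }
            for pid in self.thresholds_
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path, **params) -> "NSDispatcher":
        """Rebuild a fitted dispatcher from its JSON threshold table."""
        src = Path(source)
        text = src.read_text() if src.exists() else str(source)
        obj = json.loads(text)
        model = cls(**params)
        model.thresholds_ = {pid: float(v["t"]) for pid, v in obj.items()}
        model.normal_pre_rr_ = {
            pid: float(v["normal_pre_rr"]) for pid, v in obj.items()
        }
        model.signatures_ = {
            pid: Signature(
                np.array([row[0] for row in v["signature"]]),
                np.array([row[1] for row in v["signature"]]),
            )
            for pid, v in obj.items()
        }
        model.classes_ = np.array(["N", "S"])
        return model
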