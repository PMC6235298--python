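"""Confusion matrices and AAMI-convention metrics.

Sensitivity Se = TP/(TP+FN) and positive predictivity +P = TP/(TP+FP) are
reported per class; overall accuracy aggregates the diagonal.  Under the
AAMI no-penalty convention, beats whose *true* class is F or Q do not
count as false positives against N, S or V and are excluded from the
denominator of overall accuracy — fusion and unknown beats are considered
intrinsically unclassifiable.  For comparison under the AAMI2 scheme,
F and Q are merged into V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pyrabeat.io import AAMI_CLASSES


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (class absent or never predicted)."""


@dataclass
class ConfusionMatrix:
    """Beat counts cross-tabulated by (true class, predicted class)."""

    table: pd.DataFrame  # rows: true, columns: predicted, both AAMI order

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def __getitem__(self, key: tuple[str, str]) -> int:
        true, pred = key
        return int(self.table.loc[true, pred])

    def __str__(self) -> str:
        return self.table.to_string()


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    """Exact 5x5 cross-tabulation of true vs predicted AAMI labels."""
    true = np.asarray(true_labels, dtype=object).astype(str)
    pred = np.asarray(pred_labels, dtype=object).astype(str)
    if len(true) != len(pred):
        raise ValueError("true and predicted label lists must align")
    for arr, name in ((true, "true"), (pred, "predicted")):
        bad = set(arr) - set(AAMI_CLASSES)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    table = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(pred, name="predicted")
    ).reindex(
        index=list(AAMI_CLASSES), columns=list(AAMI_CLASSES), fill_value=0
    ).fillna(0).astype(int)
    table.index.name, table.columns.name = "true", "predicted"
    return ConfusionMatrix(table)


def class_metrics(
    cm: ConfusionMatrix, cls: str, no_penalty_fq: bool = True
) -> tuple[float, float]:
    """Sensitivity and positive predictivity for one of N, S, V.

    With ``no_penalty_fq`` (the AAMI convention), predictions made on
    beats whose true class is F or Q are not counted as false positives.

    Raises
    ------
    UndefinedMetricError
        If the class has no true beats (Se undefined) or is never
        predicted (+P undefined).
    """
    if cls not in ("N", "S", "V"):
        raise ValueError("per-class metrics are defined for N, S and V")
    t = cm.table
    tp = int(t.loc[cls, cls])
    fn = int(t.loc[cls].sum()) - tp
    fp_rows = [c for c in AAMI_CLASSES if c != cls]
    if no_penalty_fq:
        fp_rows = [c for c in fp_rows if c not in ("F", "Q")]
    fp = int(t.loc[fp_rows, cls].sum())
    if tp + fn == 0:
        raise UndefinedMetricError(f"no true {cls} beats: sensitivity undefined")
    if tp + fp == 0:
        raise UndefinedMetricError(
            f"class {cls} never predicted: positive predictivity undefined"
        )
    return tp / (tp + fn), tp / (tp + fp)


def overall_accuracy(
    cm: ConfusionMatrix,
    no_penalty_fq: bool = True,
    convention: str = "diagonal",
) -> float:
    """Overall accuracy of the classification.

    ``convention="diagonal"`` is the fraction of correctly labeled beats
    (trace over total).  ``convention="ovr"`` averages the one-vs-rest
    (TP+TN)/total over the classes N, S and V.  With ``no_penalty_fq``,
    beats whose true class is F or Q are excluded from the count.
    """
    t = cm.table
    rows = ["N", "S", "V"] if no_penalty_fq else list(AAMI_CLASSES)
    sub = t.loc[rows]
    total = int(sub.to_numpy().sum())
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    if convention == "diagonal":
        correct = sum(int(sub.loc[c, c]) for c in rows if c in sub.columns)
        return correct / total
    if convention == "ovr":
        accs = []
        for cls in ("N", "S", "V"):
            tp = int(sub.loc[cls, cls]) if cls in sub.index else 0
            fn = (int(sub.loc[cls].sum()) - tp) if cls in sub.index else 0
            fp = int(sub.loc[[r for r in rows if r != cls], cls].sum())
            tn = total - tp - fn - fp
            accs.append((tp + tn) / total)
        return float(np.mean(accs))
    raise ValueError(f"unknown accuracy convention {convention!r}")


def to_aami2(labels) -> np.ndarray:
    """Merge F and Q into V (the AAMI2 labeling); N and S unchanged."""
    arr = np.asarray(labels, dtype=object).astype(str)
    bad = set(arr) - set(AAMI_CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return np.where(np.isin(arr, ["F", "Q"]), "V", arr).astype(str)
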