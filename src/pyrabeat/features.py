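"""Per-beat feature extraction: rhythm, higher-order statistics, wavelets.

Every beat is summarized by 32 numbers: the pre- and post-RR intervals
(rhythm), the skewness and kurtosis of the amplitude samples inside the
beat window (shape), and 28 Haar detail coefficients from decomposition
levels 4-7 (multi-band morphology).  Different stages of the pyramid model
look at different projections of this vector: the N/S dispatcher sees only
rhythm, the N-group refiner sees everything, and the S-group refiner sees
everything except rhythm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt

from pyrabeat.preprocess import BeatSegment, WINDOW_LENGTH

#: Detail-band lengths at levels 4..7 in the 32-feature layout.
BAND_LENGTHS = {4: 15, 5: 7, 6: 4, 7: 2}

FEATURE_NAMES: tuple[str, ...] = (
    "preRR",
    "postRR",
    "skewness",
    "kurtosis",
    *[f"cD4_{i}" for i in range(15)],
    *[f"cD5_{i}" for i in range(7)],
    *[f"cD6_{i}" for i in range(4)],
    *[f"cD7_{i}" for i in range(2)],
)

#: Columns exposed to each stage of the model.
DISPATCHER_COLUMNS = ("preRR", "postRR")
NREFINER_COLUMNS = FEATURE_NAMES
SREFINER_COLUMNS = FEATURE_NAMES[2:]  # morphology only, no rhythm


class DegenerateInputError(ValueError):
    """Moment statistics are undefined (zero variance)."""


def skewness(samples: np.ndarray) -> float:
    """Third standardized moment with population (N-denominator) scaling.

    ``sum((x - mean)^3) / (N * s^3)`` with s the population standard
    deviation.  Measures asymmetry of the amplitude distribution; zero for
    symmetric data.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("skewness needs at least 2 samples")
    s = x.std(ddof=0)
    if s == 0:
        raise DegenerateInputError("skewness undefined for constant input")
    return float(np.sum((x - x.mean()) ** 3) / (x.size * s**3))


def kurtosis(samples: np.ndarray) -> float:
    """Fourth standardized moment, non-excess convention (normal -> 3).

    ``sum((x - mean)^4) / (N * s^4)``; large values indicate a
    heavy-tailed (peaky) amplitude distribution, as produced by a narrow
    QRS complex on a flat baseline.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("kurtosis needs at least 2 samples")
    s = x.std(ddof=0)
    if s == 0:
        raise DegenerateInputError("kurtosis undefined for constant input")
    return float(np.sum((x - x.mean()) ** 4) / (x.size * s**4))


def wavelet_features(
    window: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Haar detail coefficients at levels 4-7 for one beat window.

    The window is decomposed with the Haar wavelet (periodized
    boundaries); each detail band is truncated, or zero-padded, to the
    fixed layout lengths (15, 7, 4, 2).
    """
    window = np.asarray(window, dtype=float)
    if len(window) != WINDOW_LENGTH:
        raise ValueError(
            f"beat window must have {WINDOW_LENGTH} samples, got {len(window)}"
        )
    coeffs = pywt.wavedec(window, "haar", mode="periodization", level=7)
    # coeffs = [cA7, cD7, cD6, cD5, cD4, cD3, cD2, cD1]
    bands = {7: coeffs[1], 6: coeffs[2], 5: coeffs[3], 4: coeffs[4]}
    out = []
    for level in (4, 5, 6, 7):
        want = BAND_LENGTHS[level]
        band = bands[level][:want]
        if len(band) < want:
            band = np.pad(band, (0, want - len(band)))
        out.append(band)
    return tuple(out)


def extract_features(segments: list[BeatSegment]) -> pd.DataFrame:
    """Build the 32-column feature table for a list of beat segments.

    Returns a DataFrame with the canonical feature columns plus
    ``beat_index`` and ``label``.
    """
    rows = []
    for seg in segments:
        cd4, cd5, cd6, cd7 = wavelet_features(seg.window)
        rows.append(
            [seg.pre_rr, seg.post_rr, skewness(seg.window), kurtosis(seg.window)]
            + list(cd4) + list(cd5) + list(cd6) + list(cd7)
        )
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["beat_index"] = [seg.beat_index for seg in segments]
    df["label"] = [seg.label for seg in segments]
    return df


def zscore_by_recording(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Center and scale each feature column by the recording's own moments.

    Uses the population standard deviation; zero-variance columns are
    centered and passed through (all zeros).  Normalizing per recording
    removes patient-level offset and gain differences before the
    classifiers compare beats across patients.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        squeeze = True
    else:
        squeeze = False
    if arr.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 beats")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (arr - mean) / sd_safe
    if squeeze:
        out = out[:, 0]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def assemble_features(features: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Project the full feature table onto the view one model stage uses.

    ``mode="dispatcher"`` keeps only (preRR, postRR); ``"nrefiner"`` keeps
    all 32 features; ``"srefiner"`` keeps the 30 morphology features
    (rhythm excluded, since ventricular beats can be as premature as
    supraventricular ones).
    """
    if mode == "dispatcher":
        cols = DISPATCHER_COLUMNS
    elif mode == "nrefiner":
        cols = NREFINER_COLUMNS
    elif mode == "srefiner":
        cols = SREFINER_COLUMNS
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return features.loc[:, list(cols)]
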