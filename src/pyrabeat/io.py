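"""Reading and writing single-lead ECG recordings with beat annotations.

Implements a self-contained reader/writer for the WFDB (PhysioBank) dialect:
a text ``.hea`` header, a binary ``.dat`` signal file (formats 16 and 212),
and a MIT-format ``.atr`` beat-annotation file.  Also provides the mapping
from the 15 original beat symbols to the five AAMI super-classes and the
canonical inter-patient DS1/DS2 division of the MIT-BIH arrhythmia database.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: Original MIT-BIH beat symbols -> AAMI super-class.
AAMI_MAP: dict[str, str] = {
    # Normal-like
    "N": "N",  # normal beat
    "L": "N",  # left bundle branch block beat
    "R": "N",  # right bundle branch block beat
    "e": "N",  # atrial escape beat
    "j": "N",  # nodal (junctional) escape beat
    # Supraventricular ectopic
    "A": "S",  # atrial premature beat
    "a": "S",  # aberrated atrial premature beat
    "J": "S",  # nodal (junctional) premature beat
    "S": "S",  # supraventricular premature beat
    # Ventricular ectopic
    "V": "V",  # premature ventricular contraction
    "E": "V",  # ventricular escape beat
    # Fusion
    "F": "F",  # fusion of ventricular and normal beat
    # Unknown / paced
    "/": "Q",  # paced beat
    "f": "Q",  # fusion of paced and normal beat
    "Q": "Q",  # unclassifiable beat
}

# MIT annotation type codes <-> symbols (the subset this package emits/reads).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    28: "+", 34: "e", 35: "n", 38: "f",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# Pseudo-annotation codes that carry no beat.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class MappingError(KeyError):
    """Annotation symbol outside the recognized beat-symbol set."""


class LeadNotFoundError(ValueError):
    """Requested lead name is not present in the record header."""


def map_to_aami(symbol: str) -> str:
    """Map an original beat-annotation symbol to its AAMI super-class.

    Parameters
    ----------
    symbol : str
        One of the 15 recognized beat symbols
        (``N L R e j A a J S V E F / f Q``).

    Returns
    -------
    str
        AAMI class: ``"N"``, ``"S"``, ``"V"``, ``"F"`` or ``"Q"``.

    Raises
    ------
    MappingError
        If the symbol is not a recognized beat symbol (e.g. the rhythm
        marker ``'+'``); the caller may drop the beat.
    """
    try:
        return AAMI_MAP[symbol]
    except KeyError:
        raise MappingError(
            f"symbol {symbol!r} is not a recognized beat annotation"
        ) from None


@dataclass
class Recording:
    """One patient's single-lead ECG with beat annotations.

    Attributes
    ----------
    patient_id : str
        Record identifier (kept as a string to preserve leading digits).
    fs : float
        Sampling rate in Hz.
    signal : ndarray
        Amplitude samples in mV for the selected lead.
    r_locations : ndarray of int
        Strictly increasing sample indices of annotated R peaks.
    symbols : list of str
        Original per-beat annotation characters.
    aami_labels : list of str
        Per-beat AAMI class in {N, S, V, F, Q}.
    lead : str
        Lead name, e.g. ``"MLII"``.
    """

    patient_id: str
    fs: float
    signal: np.ndarray
    r_locations: np.ndarray
    symbols: list[str]
    aami_labels: list[str]
    lead: str = "MLII"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.r_locations = np.asarray(self.r_locations, dtype=np.int64)
        if not (len(self.r_locations) == len(self.symbols) == len(self.aami_labels)):
            raise ValueError("r_locations, symbols and aami_labels must align")
        if len(self.r_locations) > 1 and np.any(np.diff(self.r_locations) <= 0):
            raise ValueError("r_locations must be strictly increasing")
        if len(self.r_locations) and (
            self.r_locations[0] < 0 or self.r_locations[-1] >= len(self.signal)
        ):
            raise ValueError("r_locations must lie within the signal")

    @property
    def n_beats(self) -> int:
        return len(self.r_locations)

    def class_counts(self) -> dict[str, int]:
        """Number of beats per AAMI class (zero-count classes included)."""
        counts = dict.fromkeys(AAMI_CLASSES, 0)
        for lab in self.aami_labels:
            counts[lab] += 1
        return counts


@dataclass
class DatasetSplit:
    """Inter-patient division into disjoint training and test record sets."""

    ds1_ids: list[str] = field(default_factory=list)
    ds2_ids: list[str] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)


# Inter-patient division of the 44 non-paced MIT-BIH-AR records.
DS1_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DS2_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)
#: Records containing paced beats, excluded from analysis.
PACED_RECORDS = ("102", "104", "107", "217")


def interpatient_split(record_ids: list[str] | None = None) -> DatasetSplit:
    """Realize the inter-patient DS1/DS2 split over MIT-BIH-AR record ids.

    DS1 is the training set, DS2 the test set; the four paced records
    (102, 104, 107, 217) are excluded.  Unknown ids are placed in neither
    set and logged.
    """
    if record_ids is None:
        record_ids = list(DS1_RECORDS + DS2_RECORDS + PACED_RECORDS)
    split = DatasetSplit()
    for rid in record_ids:
        rid = str(rid)
        if rid in PACED_RECORDS:
            split.excluded_ids.append(rid)
        elif rid in DS1_RECORDS:
            split.ds1_ids.append(rid)
        elif rid in DS2_RECORDS:
            split.ds2_ids.append(rid)
        else:
            logger.warning("record id %r not in the inter-patient table; skipped", rid)
    return split


# ---------------------------------------------------------------------------
# WFDB dialect I/O
# ---------------------------------------------------------------------------

def _write_annotations(path: Path, samples: np.ndarray, symbols: list[str]) -> None:
    """Write a MIT-format annotation file (type code + time delta words)."""
    out = bytearray()
    prev = 0
    for samp, sym in zip(samples, symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"cannot encode annotation symbol {sym!r}")
        delta = int(samp) - prev
        prev = int(samp)
        if delta >= 1024 or delta < 0:
            # long interval: SKIP word, then the 32-bit interval, then the
            # annotation word with zero delta
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | (delta & 0x3FF))
    out += struct.pack("<H", 0)  # end of annotations
    path.write_bytes(bytes(out))


def _read_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    data = path.read_bytes()
    samples: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += delta + pending_skip
        pending_skip = 0
        sym = _CODE_TO_SYMBOL.get(code, "?")
        samples.append(t)
        symbols.append(sym)
    return np.asarray(samples, dtype=np.int64), symbols


def _pack_212(adc: np.ndarray) -> bytes:
    """Pack 12-bit two's-complement samples, two per 3 bytes."""
    adc = adc.astype(np.int32)
    if len(adc) % 2:
        adc = np.concatenate([adc, [0]])
    a = adc[0::2] & 0xFFF
    b = adc[1::2] & 0xFFF
    out = np.empty(3 * len(a), dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((a >> 8) & 0x0F) | ((b >> 8) << 4)
    out[2::3] = b & 0xFF
    return out.tobytes()


def _unpack_212(raw: bytes, n: int) -> np.ndarray:
    buf = np.frombuffer(raw, dtype=np.uint8)
    a = buf[0::3].astype(np.int32) | ((buf[1::3].astype(np.int32) & 0x0F) << 8)
    b = buf[2::3].astype(np.int32) | ((buf[1::3].astype(np.int32) >> 4) << 8)
    a[a > 2047] -= 4096
    b[b > 2047] -= 4096
    out = np.empty(a.size + b.size, dtype=np.int32)
    out[0::2] = a
    out[1::2] = b
    return out[:n]


def write_wfdb_recording(
    rec: Recording,
    directory: str | Path,
    *,
    fmt: int = 16,
    gain: float = 200.0,
    adc_zero: int = 0,
) -> Path:
    """Write a Recording as WFDB ``.hea`` + ``.dat`` + ``.atr`` files.

    Samples are quantized to ADC units as ``round(mV * gain) + adc_zero``.
    Returns the path to the header file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.patient_id
    adc = np.round(rec.signal * gain).astype(np.int32) + adc_zero
    if fmt == 16:
        adc16 = adc.astype("<i2")
        (directory / f"{name}.dat").write_bytes(adc16.tobytes())
    elif fmt == 212:
        if np.any(adc > 2047) or np.any(adc < -2048):
            raise ValueError("signal exceeds 12-bit range for format 212")
        (directory / f"{name}.dat").write_bytes(_pack_212(adc))
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    first = int(adc[0]) if len(adc) else 0
    cksum = int(np.sum(adc, dtype=np.int64) & 0xFFFF)
    header = (
        f"{name} 1 {_fmt_fs(rec.fs)} {len(rec.signal)}\n"
        f"{name}.dat {fmt} {_fmt_fs(gain)}({adc_zero})/mV 16 {adc_zero} "
        f"{first} {cksum} 0 {rec.lead}\n"
    )
    (directory / f"{name}.hea").write_text(header)
    _write_annotations(directory / f"{name}.atr", rec.r_locations, rec.symbols)
    return directory / f"{name}.hea"


def _fmt_fs(x: float) -> str:
    return f"{x:g}"


def read_wfdb_recording(
    path: str | Path, lead: str = "MLII", *, drop_unmapped: bool = True
) -> Recording:
    """Read a WFDB record (header + signal + beat annotations) for one lead.

    Parameters
    ----------
    path : str or Path
        Record path without extension (``dir/100`` reads ``dir/100.hea``,
        ``dir/100.dat`` and ``dir/100.atr``).
    lead : str
        Lead name to extract; an absent lead raises
        :class:`LeadNotFoundError` naming the available leads.
    drop_unmapped : bool
        Drop annotations whose symbol has no AAMI class (rhythm markers,
        artifacts); the dropped count is logged.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file {hea} not found")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_name, n_sig, fs_field, n_samp = lines[0].split()[:4]
    n_sig = int(n_sig)
    fs = float(fs_field.split("/")[0])
    n_samp = int(n_samp)

    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], int(parts[1].split("x")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain_s, base_s = gain_str.split("(")
            baseline = int(base_s.rstrip(")"))
        else:
            gain_s, baseline = gain_str, 0
        gain = float(gain_s) or 200.0
        desc = parts[8] if len(parts) > 8 else f"sig{len(sig_specs)}"
        sig_specs.append((fname, fmt, gain, baseline, desc))

    leads = [s[4] for s in sig_specs]
    if lead not in leads:
        raise LeadNotFoundError(
            f"lead {lead!r} not in record {rec_name}; available: {leads}"
        )
    idx = leads.index(lead)
    fname, fmt, gain, baseline, _ = sig_specs[idx]

    dat = path.parent / fname
    if not dat.exists():
        raise FileNotFoundError(f"signal file {dat} not found")
    raw = dat.read_bytes()
    if fmt == 16:
        all_adc = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        adc = all_adc.reshape(-1, n_sig)[:n_samp, idx]
    elif fmt == 212:
        all_adc = _unpack_212(raw, n_samp * n_sig)
        adc = all_adc.reshape(-1, n_sig)[:n_samp, idx]
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    signal = (adc - baseline) / gain

    atr = path.with_suffix(".atr")
    if not atr.exists():
        raise FileNotFoundError(f"annotation file {atr} not found")
    samples, symbols = _read_annotations(atr)

    keep_samples, keep_symbols, labels = [], [], []
    dropped = 0
    for samp, sym in zip(samples, symbols):
        try:
            lab = map_to_aami(sym)
        except MappingError:
            if drop_unmapped:
                dropped += 1
                continue
            raise
        keep_samples.append(samp)
        keep_symbols.append(sym)
        labels.append(lab)
    if dropped:
        logger.warning(
            "record %s: dropped %d annotations with unmapped symbols",
            rec_name, dropped,
        )
    return Recording(
        patient_id=rec_name,
        fs=fs,
        signal=signal,
        r_locations=np.asarray(keep_samples, dtype=np.int64),
        symbols=keep_symbols,
        aami_labels=labels,
        lead=lead,
    )


def resample_recording(rec: Recording, target_fs: float = 360.0) -> Recording:
    """Resample a recording to ``target_fs`` with polyphase filtering.

    R-peak indices are rescaled by ``target_fs / rec.fs`` and rounded
    half-up; an already-matching rate returns the recording unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    signal = resample_poly(rec.signal, ratio.numerator, ratio.denominator)
    n_out = int(round(len(rec.signal) * target_fs / rec.fs))
    if len(signal) > n_out:
        signal = signal[:n_out]
    elif len(signal) < n_out:
        signal = np.pad(signal, (0, n_out - len(signal)))
    scale = target_fs / rec.fs
    r_locs = np.floor(rec.r_locations * scale + 0.5).astype(np.int64)
    r_locs = np.clip(r_locs, 0, len(signal) - 1)
    return Recording(
        patient_id=rec.patient_id,
        fs=target_fs,
        signal=signal,
        r_locations=r_locs,
        symbols=list(rec.symbols),
        aami_labels=list(rec.aami_labels),
        lead=rec.lead,
    )
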