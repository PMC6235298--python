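"""Annotated synthetic ECG generator with the statistical structure the
classifier exploits.

The generator emulates exactly the properties the pyramid model relies
on: supraventricular (S) beats share the normal QRS morphology but arrive
early (shortened pre-RR, followed by a compensatory pause); ventricular
(V) beats keep a normal rhythm but have a widened QRS, no P wave and an
inverted T wave; fusion (F) beats average the two morphologies.  Additive
white Gaussian noise and sinusoidal baseline wander reproduce the two
artifacts the preprocessing stage removes.  It does not attempt
physiologically detailed ECG synthesis (no heart-rate variability
spectrum, no respiration coupling, single lead only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pyrabeat.io import Recording

#: Representative original annotation symbol written per AAMI class.
_CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "Q"}

# Gaussian wave parameters: (center s relative to R, amplitude mV, width s)
_N_WAVES = (
    (-0.17, 0.12, 0.022),   # P
    (-0.030, -0.12, 0.010),  # Q
    (0.0, 1.10, 0.011),      # R
    (0.030, -0.25, 0.011),   # S
    (0.25, 0.30, 0.035),     # T
)

#: Template span around the R peak, seconds.
_TEMPLATE_PRE, _TEMPLATE_POST = 0.25, 0.45


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic patient recording.

    Defaults describe a mildly arrhythmic ambulatory recording: 75 bpm
    base rhythm with small sinus variability, 8% supraventricular and 8%
    ventricular ectopy, 25 dB additive noise and sub-Hz baseline wander.
    """

    fs: float = 360.0
    duration: float = 180.0  # seconds
    base_rr_mean: float = 0.8  # seconds
    base_rr_sd: float = 0.05
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"N": 0.82, "S": 0.08, "V": 0.08, "F": 0.02}
    )
    s_prerr_ratio_range: tuple[float, float] = (0.55, 0.80)
    v_qrs_width_scale: float = 2.0
    noise_snr_db: float | None = 25.0
    wander_amp: float = 0.10  # mV
    wander_freqs: tuple[float, ...] = (0.21, 0.33)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        unknown = set(self.class_mix) - {"N", "S", "V", "F", "Q"}
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        if self.class_mix.get("S", 0.0) > 0.5:
            raise ValueError(
                "S proportion > 0.5 is infeasible: every premature beat needs "
                "a following beat to absorb the compensatory pause"
            )
        lo, hi = self.s_prerr_ratio_range
        if not (0 < lo <= hi < 1):
            raise ValueError("s_prerr_ratio_range must satisfy 0 < low <= high < 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


def beat_template(cls: str, fs: float = 360.0, cfg: SyntheticConfig | None = None):
    """Sum-of-Gaussians P-QRS-T waveform for one beat class.

    Returns ``(waveform, r_index)``: the template samples and the index of
    the R peak within them.  S beats reuse the N template exactly (they
    differ only in rhythm); V widens the QRS by ``v_qrs_width_scale``,
    drops the P wave and inverts the T wave; F is the elementwise mean of
    the N and V templates.
    """
    cfg = cfg or SyntheticConfig()
    if cls in ("N", "S"):
        waves = _N_WAVES
    elif cls == "V":
        w = cfg.v_qrs_width_scale
        waves = (
            (-0.030, -0.12, 0.010 * w),
            (0.0, 1.00, 0.011 * w),
            (0.030, -0.25, 0.011 * w),
            (0.25, -0.30, 0.045),
        )
    elif cls == "F":
        n_wave, r_idx = beat_template("N", fs, cfg)
        v_wave, _ = beat_template("V", fs, cfg)
        return (n_wave + v_wave) / 2.0, r_idx
    else:
        raise ValueError(f"no template for class {cls!r}")
    pre = int(round(_TEMPLATE_PRE * fs))
    post = int(round(_TEMPLATE_POST * fs))
    t = (np.arange(pre + post) - pre) / fs
    out = np.zeros_like(t)
    for center, amp, width in waves:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out, pre


def generate_rhythm(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[str]]:
    """Draw beat times (seconds) and AAMI labels for one recording.

    Inter-beat intervals are Normal(base_rr_mean, base_rr_sd) truncated
    positive.  An S beat's preceding interval is shortened by a ratio
    drawn from ``s_prerr_ratio_range``; the deficit is added to the
    following interval (compensatory pause), restoring phase and keeping
    the next beat's pre-RR at or above the base rhythm.  Two consecutive
    S beats are not generated (the second would have no normal interval
    to shorten).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])

    times = [0.5]  # leave room for the first beat window
    labels = ["N"]
    carry = 0.0
    while True:
        base = rng.normal(cfg.base_rr_mean, cfg.base_rr_sd)
        base = max(base, 0.3)
        cls = rng.choice(classes, p=probs)
        if cls == "S" and labels[-1] == "S":
            cls = "N"
        if cls == "S":
            ratio = rng.uniform(*cfg.s_prerr_ratio_range)
            interval = base * ratio + carry
            carry = base * (1.0 - ratio)
        else:
            interval = base + carry
            carry = 0.0
        t = times[-1] + interval
        if t > cfg.duration - 0.5:
            break
        times.append(t)
        labels.append(cls)
    return np.asarray(times), labels


def generate_beat_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Rhythm-only beat table: pre/post RR (s) and label per interior beat.

    Skips the waveform synthesis entirely; useful wherever only rhythm is
    needed (dispatcher training and evaluation).
    """
    times, labels = generate_rhythm(cfg)
    rows = []
    for i in range(1, len(times) - 1):
        rows.append(
            {
                "preRR": times[i] - times[i - 1],
                "postRR": times[i + 1] - times[i],
                "label": labels[i],
            }
        )
    return pd.DataFrame(rows)


def two_cluster_beat_table(
    n_beats: int = 200,
    s_fraction: float = 0.1,
    delta: float = 0.6,
    base_rr: float = 0.8,
    jitter: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Idealized rhythm table: N beats at the base pre-RR, S beats at delta times it.

    A direct realization of the separation the dispatcher rules assume —
    normal beats with pre-RR and post-RR near ``base_rr``, ectopic beats
    with pre-RR shortened by the factor ``delta``.  The jitter is bounded
    (uniform on ±``jitter`` seconds) so the two clusters are genuinely
    disjoint whenever their separation exceeds the jitter span, which is
    the premise the exact-recovery properties rely on.  No waveforms or
    compensatory-pause bookkeeping; used to study threshold recovery in
    isolation.
    """
    if not (0 < delta < 1):
        raise ValueError("delta must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.where(rng.random(n_beats) < s_fraction, "S", "N")
    pre = base_rr + rng.uniform(-jitter, jitter, n_beats)
    n_s = int((labels == "S").sum())
    pre[labels == "S"] = delta * base_rr + rng.uniform(-jitter, jitter, n_s)
    post = base_rr + rng.uniform(-jitter, jitter, n_beats)
    return pd.DataFrame({"preRR": pre, "postRR": post, "label": labels})


def generate_recording(
    cfg: SyntheticConfig, patient_id: str = "syn000"
) -> Recording:
    """Generate a fully annotated synthetic single-lead ECG recording.

    Beat waveforms are placed at the rhythm-generated R locations, then
    sinusoidal baseline wander (random phases) and white Gaussian noise
    at ``noise_snr_db`` relative to the clean signal power are added.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times, labels = generate_rhythm(cfg, rng)
    n_samples = int(round(cfg.duration * cfg.fs))
    signal = np.zeros(n_samples)
    r_locations = np.round(times * cfg.fs).astype(np.int64)

    templates = {c: beat_template(c, cfg.fs, cfg) for c in set(labels)}
    for loc, cls in zip(r_locations, labels):
        wave, r_idx = templates[cls]
        start = loc - r_idx
        end = start + len(wave)
        ws, we = max(0, -start), len(wave) - max(0, end - n_samples)
        signal[max(0, start) : min(end, n_samples)] += wave[ws:we]

    clean_power = np.mean(signal**2)

    if cfg.wander_amp > 0 and cfg.wander_freqs:
        t = np.arange(n_samples) / cfg.fs
        for f in cfg.wander_freqs:
            phase = rng.uniform(0, 2 * np.pi)
            signal += cfg.wander_amp * np.sin(2 * np.pi * f * t + phase)

    if cfg.noise_snr_db is not None and clean_power > 0:
        noise_power = clean_power / (10 ** (cfg.noise_snr_db / 10))
        signal = signal + rng.normal(0.0, np.sqrt(noise_power), n_samples)

    return Recording(
        patient_id=patient_id,
        fs=cfg.fs,
        signal=signal,
        r_locations=r_locations,
        symbols=[_CLASS_SYMBOL[c] for c in labels],
        aami_labels=list(labels),
        lead="MLII",
    )


def generate_patients(
    n_patients: int, cfg: SyntheticConfig, base_seed: int = 0
) -> list[Recording]:
    """Generate a cohort of independent synthetic patients.

    Each patient gets its own seed derived from ``base_seed`` so cohorts
    with different base seeds are disjoint in randomness.
    """
    from dataclasses import replace

    out = []
    for i in range(n_patients):
        pcfg = replace(cfg, seed=(base_seed * 100003 + i) % (2**31 - 1))
        out.append(generate_recording(pcfg, patient_id=f"syn{base_seed}_{i:03d}"))
    return out
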