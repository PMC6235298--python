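# Methods

This note documents the models, numerical choices and limitations behind
`pyrabeat`. It describes what the code computes and why the open design
choices were resolved the way they were; every empirical figure quoted
here is produced by the test suite or `scripts/acceptance.py`.

## Problem setting

Input is a single-lead ECG (modified limb lead II) with annotated R-peak
locations and per-beat labels in the five AAMI classes {N, S, V, F, Q}.
Evaluation follows the inter-patient paradigm: models are trained on one
set of patients (DS1 of the MIT-BIH arrhythmia database, 22 records) and
evaluated on a disjoint set (DS2, 22 records); the four paced records
(102, 104, 107, 217) are excluded. All recordings are resampled to
360 Hz before processing (band-limited polyphase resampling; annotation
indices rescaled by the rate ratio and rounded half-up).

## Preprocessing

**Baseline wander** is estimated by a 200 ms median filter followed by a
600 ms median filter and subtracted. Filter widths are `round(fs·0.2)`
and `round(fs·0.6)` samples, incremented to the next odd integer so the
filters are symmetric (73 and 217 samples at 360 Hz); edges use reflect
padding. A known property of this cascade is that it absorbs a small
share of broad-wave content: on a noise-free synthetic recording the
removed "baseline" carries roughly 2–3% of the signal RMS, originating
from P/T-wave tails that a median filter cannot distinguish from drift.
The pipeline-fidelity test therefore asserts < 5% RMS distortion on
clean input rather than exact recovery.

**Denoising** decomposes the baseline-corrected recording with the
Daubechies-4 wavelet (orthogonal, short vanishing moment — appropriate
for the abrupt QRS transitions), 6 levels, periodized boundaries, and
hard-thresholds the detail coefficients. Two threshold rules are
provided:

* `universal` (default): T = √(2 ln n)·σ̂ with σ̂ = MAD(cD1)/0.6745,
  the standard universal-threshold estimate of the noise scale from the
  finest detail band;
* `two-log-n`: T = 2·log n applied to the coefficients of the
  amplitude-normalized signal. This form has no noise-scale anchor and
  is kept only for comparison; on unnormalized millivolt data it would
  zero essentially all coefficients.

Hard thresholding only removes coefficients, so output energy never
exceeds input energy (orthogonality + Parseval). With thresholding
disabled the transform reconstructs the input to < 1e−8.

**Segmentation** cuts one window per annotated R peak: 90 samples
(250 ms) before the peak, the R sample itself, and 144 samples (400 ms)
after — 235 samples in total, the R sample included. Beats lacking a
previous or next neighbor
(undefined pre-/post-RR) or sufficient signal on either side are dropped.
All indices are 0-based; windows are half-open `[r−90, r+145)`.

## Features (32 per beat)

| block | features | count |
|---|---|---|
| rhythm | preRR, postRR (seconds) | 2 |
| shape statistics | skewness, kurtosis of the window | 2 |
| wavelet | Haar detail coefficients, levels 4–7 | 15 + 7 + 4 + 2 |

Skewness and kurtosis use population (N-denominator) moments,
Σ(Xᵢ−X̄)³/(N·s³) and Σ(Xᵢ−X̄)⁴/(N·s⁴); kurtosis is non-excess (normal
≈ 3). Constant windows are a degenerate-input error.

The Haar decomposition of a 235-sample window uses periodized boundaries,
giving bands of length 15/8/4/2 at levels 4–7; no standard boundary
convention yields the canonical 15/7/4/2 layout simultaneously, so each
band is truncated (or zero-padded) to those lengths. The layout is the
single deviation knob of the feature module. Periodization of an
odd-length signal involves boundary padding, so exact Parseval identity
holds on dyadic lengths; the invariant is tested there.

Per-recording normalization: all 32 features are z-scored with the
recording's own mean and population SD before entering the refiners,
removing patient-level offset and gain. Rhythm enters the *dispatcher*
in raw seconds instead — the rules are scale-free ratios, and z-scoring
pre-RR first would put the denominator near zero and destabilize them.

## Level 1: the N/S dispatcher

A beat is labeled S when either rule fires (strict `<`):

* rule 1: (preRR − postRR)/normalPreRR < t (premature beat followed by a
  compensatory pause),
* rule 2: (preRR − normalPreRR)/normalPreRR < t (premature relative to
  the patient's own rhythm).

**Training** (per training patient): normalPreRR is the median pre-RR of
the patient's N beats; t is chosen from the grid {−0.05, …, −0.95}
(step 0.05, the open interval (−1, 0)) to maximize
N-sensitivity + S-sensitivity over the patient's N/S beats. Ties resolve
to the least negative t, which minimizes false-S labeling at equal
objective. Patients with no S beats receive the sentinel t = 0 and skip
the search; a patient with no N beats is a training error. V/F/Q beats
are ignored at this level.

**Prediction** (per test patient):

1. normalPreRR is estimated robustly: Tukey fences (1.5×IQR, quartiles
   by linear interpolation) flag outliers; if at most 10% of pre-RRs are
   outliers the median is used, otherwise the mean of (outlier mean,
   overall median) — guarding against recordings where ectopy is frequent
   enough to drag the median itself.  Exactly 10% takes the median
   branch.
2. The threshold is transferred from the training patient whose
   z-scored pre-RR distribution is nearest in earth mover's distance
   (signatures: equal-width 10-bin histograms, empty bins dropped,
   cluster mean + mass fraction); nearest means *minimum* EMD.
3. A sentinel neighbor (t = 0) is replaced by the most negative
   threshold in the table: a potential S beat should never be missed
   because the nearest training patient happened to have none. If every
   threshold is the sentinel (degenerate all-normal training set), the
   dispatcher falls back to t = −0.05 with a warning rather than t = 0,
   which would label any beat with preRR < postRR as S.

Because the rules are strict thresholds, the set of S-labeled beats is
non-increasing as t decreases (property-tested).

## Earth mover's distance

Signatures are weighted cluster sets {(pᵢ, wᵢ)}. The distance is the
minimum total work Σ fᵢⱼ·dᵢⱼ over flows fᵢⱼ ≥ 0 with row sums ≤ source
weights, column sums ≤ sink weights and total flow equal to the smaller
total mass, normalized by the total flow; ground distance dᵢⱼ = |pᵢ−qⱼ|.
The LP is solved exactly (HiGHS), which handles unequal-mass signatures;
for normalized 1-D signatures the result equals the closed-form 1-D
Wasserstein distance, which serves as an independent oracle in tests
(agreement < 1e−9 on 200 random pairs) and is never used as the
implementation.

## Level 2: the refiners

* `NRefiner` ({N, V, F, Q}, 32 features): seven base classifiers —
  linear-kernel SVM, RBF SVM (γ scaled), decision tree (min leaf 5),
  5-NN, logistic regression, perceptron, Gaussian naive Bayes — each
  preceded by a standardizer and trained on its own class-balanced
  resample (every class drawn to the median class count; majority
  classes undersampled without replacement, minorities bootstrapped).
  Aggregation is majority vote; ties break by the fixed priority
  V > F > Q > N, favoring disease sensitivity. The members'
  hyperparameters are fixed, documented, deliberately off-the-shelf
  defaults.
* `SRefiner` ({S, V, F, Q}, 30 features — no rhythm, because V beats can
  be as premature as S beats): a single standardized RBF SVM with
  balanced class weights.

Both refiners train on ground-truth groups (all DS1 beats with labels in
their class set), not on dispatcher-routed beats, so refiner quality is
decoupled from dispatcher errors. Classes absent from training are
removed from the model's class set with a warning. All stochastic
components (resampling, SVM internals) derive from one run-level seed.

Routing is structural: a beat can only receive final label N if level 1
put it in the N group, and only S if level 1 put it in the S group.

## Evaluation

Per class c ∈ {N, S, V}: Se = TP/(TP+FN), +P = TP/(TP+FP). Overall
accuracy is the fraction of correctly labeled beats (trace convention);
a one-vs-rest (TP+TN)/Σ variant is also provided since published
accuracy figures do not state their convention. Under the AAMI
no-penalty convention (default), beats whose *true* class is F or Q are
excluded from false-positive counts against N/S/V and from the accuracy
denominator. The AAMI2 relabeling merges F and Q into V for
cross-database comparisons. Undefined metrics (zero denominators) raise
rather than silently reporting 0.

## Synthetic data

The generator emulates precisely the structure the model exploits:

* beat morphology: sum-of-Gaussians P-QRS-T templates. S shares N's
  template exactly; V widens the QRS by 2.0×, drops the P wave and
  inverts the T wave (lowering kurtosis, the direction the shape
  statistics rely on); F is the elementwise mean of N and V. T-wave
  parameters (peak 250 ms after R, σ = 35 ms) are physiological.
* rhythm: inter-beat intervals Normal(0.8 s, 0.05 s) truncated at 0.3 s.
  An S beat's preceding interval is shortened by a ratio drawn uniformly
  from (0.55, 0.80); the deficit is added to the following interval — a
  compensatory pause restoring phase, which is exactly the regularity
  rule 1 assumes. Consecutive S beats are not generated. V beats keep a
  normal rhythm so that their detection must come from morphology.
* artifacts: sinusoidal baseline wander (0.1 mV at 0.21 and 0.33 Hz,
  random phases) and white Gaussian noise at 25 dB SNR.
* defaults: 360 Hz, 180 s per patient (~220 beats), class mix
  N 0.82 / S 0.08 / V 0.08 / F 0.02. Q beats are not generated by
  default (their real-world counts are single digits per database).

What passing tests on this generator do **not** show: robustness to
real-world morphology variability within a class, atrial-fibrillation
rhythms where the pre-RR rules are known to fire spuriously, electrode
artifacts, or lead placement differences. The generator is a test of the
algorithmic contract, not a clinical validation.

A second, idealized rhythm-only fixture (`two_cluster_beat_table`) draws
N beats at the base pre-RR and S beats at δ× the base with *bounded*
uniform jitter (±0.05 s), so the two clusters are genuinely disjoint
whenever their separation exceeds the jitter span — the premise of the
exact threshold-recovery property (perfect per-patient training
objective and ≥ 0.95 held-out S sensitivity for δ ≤ 0.7).

## Problem sizes

The shipped verification runs use: 30 independent cohorts of 3 training
+ 2 held-out synthetic patients (~1 100 training / 440 test beats per
cohort) for the end-to-end benchmark; 50 seeds × 10 training + 10
held-out two-cluster patients (220 beats each) for threshold recovery;
200 random signature pairs for the EMD oracle; 100 Monte-Carlo draws at
5 dB input SNR for the denoising gain. `scripts/acceptance.py` uses 10
cohorts and 25 recovery seeds. These sizes give stable aggregate
metrics (thousands of evaluated beats per quantity) while keeping a full
run in tens of seconds.

## Known limitations

* The WFDB reader/writer implements the subset of the dialect this
  package needs (text headers, formats 16 and 212, beat annotations with
  skip/aux handling); obscure header features (multi-segment records,
  non-trivial counter frequencies) are out of scope.
* Published benchmark figures for two-level models of this family do not
  pin down the ensemble members' hyperparameters, so they are not
  bit-reproducible here; the package's claims rest on the synthetic
  benchmark and property tests instead.
* Lead II is assumed present under the name `MLII` (or `II` for
  INCART-style headers); records with anomalous lead ordering need an
  explicit `lead=` override.
* The dispatcher assumes every patient has identifiable N beats; a
  recording that is entirely ectopic is a training error by design.
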