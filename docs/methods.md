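# Methods

This note documents the models, parameter choices and numerical conventions
behind `wavebeat`, and what the synthetic test bed does and does not show.

## Wavelet machinery

Two orthogonal filter banks are embedded as named constants: Symlet-8
(16 taps, 8 vanishing moments) and Haar (used mainly as a transparent test
case). The high-pass filter is derived from the scaling filter by the
quadrature-mirror relation g[k] = (−1)^k h[L−1−k], and both identities
Σh = √2 and Σh² = 1 are enforced to 1e−12 at import time, so the bank has
no external coefficient source; a unit test additionally cross-checks the
constants against PyWavelets' sym8 to 1e−15.

*Decimated transform.* `dwt_multilevel`/`idwt_multilevel` delegate to
PyWavelets' `wavedec`/`waverec` built from these banks. Boundary handling:
`symmetric` (default, standard half-sample symmetric extension; level-j
coefficient blocks have length ⌊(n_{j−1}+L−1)/2⌋) or `periodic`
(periodization; length ⌈n_{j−1}/2⌉, orthogonal, energy conserving).
Downstream code never hard-codes coefficient lengths — it asks the
transform (`approx_length`), which is the single source of truth. The
periodized path is verified coefficient-for-coefficient against a
brute-force circular-convolution oracle, with the decimation phase fixed at
the filter half-length L/2 (the group delay of these even-length filters).

*MODWT.* The maximal overlap DWT is implemented directly with the circular
pyramid algorithm: per level j the base filters, rescaled by 2^(−1/2), are
applied with stride 2^(j−1) (Percival–Walden convention). Every coefficient
sequence keeps the input length; the transform is energy preserving and —
because each level is a fixed circular convolution evaluated tap-by-tap in
a deterministic order — *bitwise* shift-equivariant, which the tests assert
with exact array equality. The inverse applies the adjoint convolutions in
reverse level order. PyWavelets' `swt` is not used: its undecimated variant
omits the per-level 2^(−1/2) rescaling, so it serves only as an independent
reference point, not as the implementation.

*Multiresolution reconstruction.* `mra_reconstruct` zeroes every coefficient
sequence outside the kept set and inverts; by linearity the singleton
reconstructions sum to the full inverse (tested to 1e−8).

*Denoising.* Soft thresholding of all detail levels of a level-4 sym8
decomposition at the Donoho universal threshold σ̂√(2 ln n),
σ̂ = median(|d₁|)/0.6745, approximation untouched. No thresholding rule is
canonical for ECG; universal/soft is the standard default and the rule is a
parameter. On a 1.7 Hz sine at 5 dB input SNR the gain is ≈ +12 dB; on a
noiseless smooth signal the relative change is < 1e−10 (the threshold scales
with the estimated noise).

## R-peak detection

`ModwtPeakDetector` operates on one lead (default lead 0):

1. MODWT to 7 scales. The record is reflect-padded (min(n−1, 512) samples
   per side) first: the MODWT is circular, and without padding the
   wrap-around discontinuity injects QRS-band energy at both record edges.
2. Reconstruction keeping scales {4, 5} only. At 500 Hz these are the
   ≈ 15.6–31.2 and 7.8–15.6 Hz octaves, bracketing QRS energy while
   suppressing P/T waves (below) and noise (above). The retained set is a
   parameter; other sampling rates need a different choice.
3. The reconstruction is squared; local maxima above
   `threshold_factor` (4.0) × RMS of the squared signal are picked with a
   250 ms refractory distance (a ≈ 240 bpm ceiling, above any rhythm the
   generator produces). The threshold is adaptive per record — no absolute
   millivolt constants.
4. Each pick is refined to the sample of maximum |amplitude| of the raw
   lead within ±50 ms; picks merged by refinement keep the larger-amplitude
   sample and the refractory distance is re-enforced.
5. Candidates within 60 ms of either record edge are discarded. 60 ms is
   the QRS half-width, the same margin the generator uses to decide whether
   a partial edge beat belongs to the ground truth — a truncated QRS whose
   apex cannot be represented inside the record is neither generated as
   truth nor reported as a detection.

A flat (or all-zero) record yields an empty series, not an error. On
noise-free synthetic sinus records the detector is exact (sensitivity =
PPV = 1.0 at 50 ms tolerance, offsets ≤ 10 ms); at 10 dB white-noise SNR it
stays above 0.95 on both. Scoring uses greedy one-to-one nearest matching
within a 50 ms tolerance; an empty detection reports PPV = 0 with an
explicit `ppv_defined=False` flag.

## Synthetic ECG generator

Each beat is a sum of Gaussian bumps (offset, width, amplitude) for
P, Q, R, S, T placed at a beat center; centers follow a sampled RR
sequence. Defaults on the unit-gain lead: R (σ 12 ms, 1.0 mV),
Q/S (σ 10 ms, −0.12/−0.20 mV), P at −0.21·RR (σ 25 ms, 0.12 mV), T at
+0.30·RR (σ 60 ms, 0.28 mV). Sinus rhythm: RR ~ Normal(60/HR, cv·60/HR),
cv = 0.03, HR default 70 bpm. Rhythm classes:

- **AF** — P amplitude 0 and i.i.d. RR with cv = 0.30 at a default mean of
  150 bpm (the low end of the rapid-AF band, keeping the RR floor of 0.26 s
  clear of the detector's 250 ms refractory); after flooring, the realized
  RR coefficient of variation stays ≥ 0.2. Fibrillatory f-waves are not
  modelled — absent P plus irregular RR are the discriminative features the
  downstream stages use.
- **PVC / PAC** — each non-adjacent beat is ectopic with probability 0.15:
  the arriving interval is shortened ×0.65 and the following one lengthened
  ×1.5 (PVC, compensatory) or ×1.2 (PAC); PVC beats additionally widen the
  QRS ×2.5, drop the P wave and invert the T.
- **LBBB / RBBB** — QRS widened on every beat (RBBB adds an R' notch);
  **I-AVB** — P fixed at −320 ms (PR > 300 ms); **STD / STE** — a ∓0.15/+0.20 mV
  smooth ST bump at +110 ms.

The single waveform is replicated across 12 leads with fixed gains
(including negative aVR/V1), wander/powerline/white noise is added last,
and `snr_db` can size the white noise against the clean per-lead power.
Ground truth records every R center whose full ±60 ms QRS lies inside the
record; partial edge beats are synthesized but excluded from truth. R
centers are placed on integer samples, so on a clean record the window
maximum coincides exactly with the stored truth index.

What the generator does **not** emulate: realistic lead projections,
respiration and HRV spectra, f-waves, muscle artifact, electrode motion.
Passing tests therefore demonstrate the pipeline's mechanics and its noise
robustness in a controlled regime, not clinical performance.

## Features and classification

Beats are windowed 250 ms pre / 400 ms post R (325 samples at 500 Hz —
covers P-QRS-T at normal rates; both extents are parameters); windows
crossing a record edge are dropped and counted. The base feature vector is
the level-4 sym8 approximation block (34 coefficients for a 325-sample
beat under symmetric extension). RR context (on by default) appends the
preceding RR, following RR, and the ratio of the preceding RR to the local
8-beat mean; edge beats reuse the available neighbour. Features are
computed on the detection lead only; how 12 leads should enter a single
feature vector is genuinely open, and single-lead is the conservative
default.

Normalization is plain z-scoring fitted on the training partition only;
zero-variance columns pass through unscaled with a flag. The split is
stratified and seed-deterministic at the beat level (beats of one record
can land on both sides — record-level grouping would be the stricter
protocol for clinical claims and is out of scope here).

The classifier wraps a Gaussian-kernel SVC behind a scikit-learn estimator
(`fit`/`predict`/`decision_function`, `get_params`/`set_params`, fitted
attributes `support_vectors_`, `dual_coef_`, `intercept_`). Grid search is
a hand-written exhaustive loop over C ∈ {0.1, 1, 10, 100, 1000} ×
γ ∈ {1e−4 … 1} scored by stratified 5-fold CV accuracy, iterating in
ascending (C, γ) order with a strict-improvement update so ties resolve to
the smallest (simplest) pair deterministically. The grid bounds are
conventional decade ranges, not tuned values; the full 25-row results table
is written out for audit. Class weighting is off by default (the reference
evaluation is near-balanced, 90/88).

## Metrics

Confusion counts are tabulated exactly (rows = true, columns = predicted);
precision, recall, F1 per class, accuracy = (TP+TN)/total, macro and
support-weighted averages follow the standard definitions, with
zero-denominator cells reported as 0 plus an explicit flag. Applied to the
two integer matrices consistent with the reference per-class tables
([[86, 4], [6, 82]] and [[90, 0], [2, 86]]), the report reproduces every
printed cell to six decimals. ROC uses the grouped threshold sweep with
trapezoidal AUC; tests pin it to the Mann–Whitney pairwise statistic.

## Problem sizes and determinism

The shipped test suite and the acceptance script use synthetic problem
sizes chosen to exercise every code path at comfortable statistical margins:
10–120 s records, 20-record detector batches, and a 100-records-per-class
end-to-end run (~3 400 beats, 25-point grid × 5 folds), which completes in
well under a minute on one CPU. One integer seed drives record generation,
splitting, and CV shuffling; identical configs reproduce bit-identical
outputs, and `manifest.json` captures config + package versions per run.

## Known limitations

- Binary normal/abnormal only; the nine rhythm codes exist in the data
  model but no multiclass classifier is built.
- Single-lead detection and features; no multi-lead fusion.
- No P/T delineation or interval measurements (PR/QT/ST) beyond what the
  generator itself places.
- Synthetic validation only; CPSC-format reading is supported, but no real
  recordings (or their headline accuracies) are bundled or claimed.
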