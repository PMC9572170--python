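# Methods

`relapsekit` implements a complete computational pipeline for wearable
digital phenotyping in psychotic disorders: cleaning of raw wrist-sensor
streams, linear and nonlinear heart-rate-variability (HRV) and actigraphy
descriptors, patient-versus-control statistics, and unsupervised relapse
detection with autoencoders and decision-level fusion. Because clinical
cohorts of this kind are private, the package ships a synthetic cohort
generator whose defaults define the study conditions under which every
stage is tested.

## Signal model of the synthetic cohort

**RR intervals.** Beats are generated sequentially:
`RR(t) = b·s(t) + A_LF sin(2π·0.10·t + φ1) + A_HF sin(2π·0.25·t + φ2) + ε(t)`,
where `b` is the subject baseline (ms), `s(t)` a mild sleep bradycardia
factor (×1.10 asleep), the two sinusoids place spectral mass at the
canonical LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) bands, and `ε` is AR(1)
noise (beat-indexed, default φ = 0.8) whose marginal SD is calibrated to
the subject's target SD1. The wrist device is emulated by a 5 Hz readout
that repeats the latest beat value until the next beat, so the downstream
de-duplication rule is genuinely exercised. Artifacts are injected at
configurable rates: out-of-range RR values (per beat), non-detected pulses
(beat dropped; the readout keeps repeating), and readout gaps (Poisson
starts, mean 60 s).

**Motion.** While awake, activity follows a two-state (active/rest)
per-second Markov chain (mean bouts 15 s / 22.5 s, duty ≈ 0.4); active
seconds emit zero-mean Gaussian triaxial samples at 20 Hz whose energy is
modulated per 5-min interval; sleep is near-quiescent. The accelerometer
and gyroscope share the bout process but have independent amplitudes.
Steps are Poisson counts proportional to active seconds.

**Subject traits and effect sizes.** Each subject draws latent traits
(mean/variability of motion energy, baseline RR, SD1, LF share, sleep
timing, …) from control population distributions; `effect_sizes` shifts a
patient latent by δ population SDs. The generator inverts each calibrated
latent analytically (e.g. bout amplitude `a = sqrt(L/(3·duty))`, energy
modulation width `w = sqrt((S/L)² − CV_duty²)` with the bout-chain constant
`CV_duty = 0.283`), so the realized standardized difference of per-subject
aggregates tracks the configured δ; the test suite verifies ±0.25 fidelity
at n = 50/50 for the calibrated handles (`ste_acc_mean`, `ste_acc_std`,
`rr_mean`, `sd1_mean`). Spectral (`lf_pct_mean`) and entropy
(`sampen_mean`) handles are monotone but only approximately calibrated,
because broadband AR(1) power leaks into the LF band. Handles are
calibrated individually; strong simultaneous shifts interact mildly.

**Relapses.** Annotated episodes carry a severity (low/moderate/severe;
"mid" is accepted as moderate) scaling the configured `anomaly_magnitude`
by 0.5/1.0/1.5. Inside a relapse window the subject's latents shift
(activity down and more erratic, HR up, SD1 down, LF share up, each by a
fixed fraction of the population SD per unit magnitude); the
`prodrome_days` before onset ramp linearly up to half the full shift.
Physiological day labels use the 21-day pre-relapse window, interview
sessions the 30-day window.

**Interview sessions** are synthesized directly in the log-mel domain: a
patient-specific rank-8 bank of smooth spectral templates with AR(1)
mixture weights plus Gaussian noise renders non-negative 128×64 slices
(~1 s each, Poisson-distributed count per session); pre-relapse/relapse
states scale the mixture mean, shift it along a fixed direction, and raise
the noise floor proportionally to magnitude. No waveform-level speech is
synthesized.

**What the generator does not emulate:** physiological realism beyond
second-order statistics — no respiratory sinus arrhythmia coupling to a
breathing signal, no posture/exercise structure, no medication effects, no
realistic speech spectra. Passing tests therefore demonstrate that the
algorithms recover *planted* structure of the documented form, not
clinical validity on real patients.

## Preprocessing

5-min half-open windows anchored at subject-local midnight. RR: drop
identical consecutive readouts; remove values outside [300, 2000] ms; fill
missed-pulse gaps (inter-beat time > 1.75× the rolling 11-beat median RR)
by linear interpolation; truncate to the beats whose cumulative time lies
in the first 270 s (90%); fewer than 10 valid beats rejects the window as
sparse. Motion: windows with more than 50 missing samples (of 6000) are
rejected; the rest are nearest-neighbour filled, truncated to the first
5940 samples (99%), and denoised by suppressing the two finest db4 wavelet
detail bands per axis (a soft-threshold mode is available; the
suppression default was chosen because MAD-based universal thresholding is
inert against isolated spikes in otherwise clean windows). Day tensors
stack the 10 detection features at 5-min resolution (288×10); missing runs
of up to 10 h are median-filled from a ±1 h neighbourhood, longer runs
reject the day.

## Features

Per window: short-time energy (mean squared triaxial norm — mean rather
than sum so the value is window-length invariant); Lomb–Scargle
periodogram of the mean-centred RR sequence on a 1024-point 0.001–0.5 Hz
grid (the estimator evaluates the classical phase-shifted definition via
phasor-rotation recurrences; a `center=False` switch restores the literal
uncentred formula), with normalized band powers reported as percent of
LF+HF and their ratio; sample entropy (m = 2, r = 0.2·SD, Chebyshev,
self-matches excluded); Higuchi fractal dimension (k_max = 10);
multiscale fractal dimension via flat morphological covers (scales 1–30
samples, local log–log regression over 5-scale windows, frames of 64
samples hop 32 restricted to the boundary-unaffected region; cover
area ∼ s^(2−D), estimates clipped to [1, 2], zero-area stretches assigned
the smooth limit D = 1) summarized by fd[1], min, max, mean, std over the
full D(s,t) profile; Poincaré SD1/SD2 with SD1 = RMSSD/√2 exactly
(uncentred RMS convention) and SD2 the population SD of the rotated
along-identity coordinate; mean HR and RR; sine/cosine of seconds-of-day;
and the fraction of in-range beats (`pct_valid`). SampEn/Higuchi/MFD
parameters are conventional HRV-literature defaults, all exposed in
`FeatureConfig`. Daily step totals and the sleep/wake ratio use only days
with ≥ 20 recorded hours.

## Group statistics

Per subject and state (awake/sleep, from diary overlap of the window
midpoint), the mean and sample SD of 14 feature types give 28 aggregates.
Groups are compared feature-wise with two-tailed Mann–Whitney U tests
(exact enumeration when the combined tie-free sample is ≤ 12, otherwise
the tie-corrected normal approximation) and Benjamini–Hochberg adjustment
across the 28 features of one state run; steps/sleep-ratio checks are
adjusted separately. Medians and IQRs (Q3 − Q1, linear-interpolation
quantiles) are tabulated per group. A recorded-data balance check uses
Welch's t-test gated on Shapiro–Wilk normality with a Mann–Whitney
fallback.

A power note: with 28-feature BH control, detecting a single d = 1.0
standardized group shift at n = 20 + 20 effectively requires raw
p < 0.05/28, where the U test's power is ≈ 0.5; single-feature effects of
this size at this sample size are therefore expected to be missed more
often than found. The calibration suite measures exactly this.

## Anomaly detection

Day tensors are min-max normalized to [0, 1] per feature (fit on training
data only; sin/cos pass through; test values clipped), cut into
non-overlapping sub-sequences (default 4 h = 48 slots; the desk-scale
experiments use stride-2 tensors with 8 h windows), and reconstructed by
one of four sequence autoencoders (FNN, 1-D CNN with batch norm and
LeakyReLU, attention seq2seq GRU with hidden size 100, 4+4-layer
transformer with positional encoding and reversed-sequence decoder). MSE
loss; Adam for FNN/transformer, RMSprop for CNN/GRU; lr 1e-4 (transformer
1e-3), batch 64, up to 50 epochs with early stopping (patience 5) on the
first validation half. Audio models (CAE/CVAE on 128×64 log-mel slices)
and the 1-D CVAE on 5×30 hourly HRV tensors train with Adam, lr 3e-4,
batch 8, ≤ 200 epochs, patience 10, and variational loss
`W_MSE·MSE + W_KL·KL` with weights 1 and 0.01. All networks run on an
in-package reverse-mode autodiff engine over numpy (gradcheck-verified);
hidden widths and filter counts live in `ModelConfig` defaults.

Per-point mean-absolute-error vectors from the second validation half fit
a Gaussian (μ, Σ) with a scaled-trace ridge (1e-6·tr(Σ)/d); test points
are scored by the squared Mahalanobis distance and day-averaged.
Variational models additionally expose the latent KL divergence from
N(0, I) as a probe, and a model-free baseline applies the same Mahalanobis
scoring to raw features. 5-fold splits rotate normal days/sessions through
a 60/20/20 train/validation/test partition (validation halved into
val1/val2) at group granularity; anomalous groups join every fold's test
set (a partition mode is available); near-relapse days are discarded
throughout. ROC-AUC and PR-AUC (average precision; positive class =
relapse, base rate recorded implicitly by the day labels) are reported as
medians over folds, per patient (personalized / global-evaluated-
individually) or pooled (global). Session scores pool per-slice scores by
average, max, or p = 10 norm pooling; decision-level fusion min-max
standardizes each modality over the paired evaluation set and then adds or
multiplies day-aligned session/physiology scores.

## Numerical and protocol choices

* All randomness derives from integer `SeedSequence` chains (config seed →
  subject → day), so outputs are bit-reproducible across platforms.
* The Lomb–Scargle rotation kernel agrees with a dense direct evaluation
  of the definition to ~1e-12 relative; scipy's implementation is the
  fallback without numba and an independent oracle in tests.
* Constant features map to 0.5 under min-max normalization; all-tied
  samples return p = 1; undefined SampEn (no template matches) and zero
  LF+HF windows are flagged as NaN rather than fabricated.
* Exact-vs-asymptotic U-test switchover at combined n = 12 (ties always
  use the approximation).
* Windows are non-overlapping and contiguous; day/window boundaries are
  half-open.
* Desk-scale experiment sizes (10-patient cohorts, 14 days, stride-2
  tensors, reduced CNN filter counts, 32–64 windows per subject for
  calibration runs) are the package's default test-bench dimensions;
  all full-scale parameters remain available through the configs.

## Known limitations

* The generator's effect-size calibration is exact only for the documented
  handles and attenuates slightly (≈ 0.85–0.95) through within-subject
  sampling noise of aggregate statistics.
* Hour-tensor (Welch band-peak) features use uniform 4 Hz resampling of
  the RR series, which slightly smears power above ~0.4 Hz.
* The audio path models spectrogram statistics only; conclusions about
  speech-based detection transfer to the method, not to real speech.
* Training runs single-threaded on CPU; the architectures are faithful in
  structure but sized for desk-scale data.
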