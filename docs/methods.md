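# Methods

## Problem setting

Arterial blood pressure correlates negatively with pulse transit time (PTT):
a stiffer, higher-pressure arterial tree propagates the pulse wave faster.
The package estimates beat-to-beat systolic and diastolic pressure (SBP,
DBP, mmHg) from three noninvasive channels — ECG, finger PPG and seat-sensor
BCG — in two ways: an end-to-end CNN + Bi-GRU + attention regressor on raw
5-s windows, and a per-cycle interval-feature (RRI/PTT/RJI) multiple linear
regression. Because clinical multi-channel recordings with beat-to-beat BP
references are rarely shareable, all development and testing run on a
synthetic generator with exact planted ground truth.

## Synthetic generator

`cufflessbp.synth` emulates a seated resting acquisition at 1000 Hz. Beat
times start 0.5 s in, with per-beat heart rate `hr_mean ± hr_sd` (default
70 ± 2 bpm). Per beat i at time r_i:

* **PTT_i** = `ptt_mean + ptt_amplitude · sin(2π r_i / ptt_period_s)` —
  a slow deterministic modulation (defaults 250 ± 30 ms over 30 s) standing
  in for autonomic BP drift.
* **BP coupling**: `SBP_i = sbp_intercept + sbp_slope · PTT_i + ε`,
  ε ~ N(0, `bp_noise_sd`), slopes strictly negative (defaults
  160 − 0.18·PTT and 100 − 0.12·PTT with 1 mmHg noise, giving a cohort mean
  near 115/70 mmHg).
* **RJI_i** ~ N(`rji_mean`, `rji_sd_ms`) clipped into [112, 248] ms
  (defaults 180 ± 5 ms). The jitter is independent of PTT so the MLR design
  matrix is full-rank and the two predictors are identifiable.

Morphology is deliberately schematic — only timing and coupling are
load-bearing: the ECG beat is a sum of Gaussians (P/Q/R/S/T lobes, sharp R),
the PPG pulse is a raised-cosine rise (150 ms) and decay (450 ms) whose
steepest-rising point sits exactly 75 ms after onset (`PPG_DPEAK_OFFSET_MS`,
so a measured R→dPPG interval equals planted PTT + 75 ms), and the BCG J
wave is a Ricker wavelet (σ = 15 ms). Additive disturbances per channel: a
0.25 Hz baseline-wander sinusoid, a power-line sinusoid (default 60 Hz) and
white noise. Ground truth (fiducial times, PTT, RJI, per-beat BP) is frozen
before noise injection, so noise settings never perturb it.

What the generator does **not** emulate: pulse-morphology changes with BP,
motion artifacts, respiration, arrhythmias, sensor drift or realistic
hemodynamics. Passing tests therefore demonstrate the pipeline's
correctness and its ability to recover planted timing/coupling — not
clinical accuracy on real subjects.

## Preprocessing

Per channel, a zero-phase (forward–backward) 2nd-order Butterworth band-pass
(ECG 0.5–35 Hz, BCG 4–15 Hz, PPG 0.5–15 Hz); zero-phase filtering is chosen
so fiducial timings are not skewed by group delay. The whole record is then
polyphase-resampled to 125 Hz, and 5-s windows (625 samples) are cut with a
configurable stride; the minimum shift at 125 Hz is one sample (8 ms), and
`stride_s` defaults accordingly to 0.008 s. Each window's target is the beat
annotation in force (sample-and-hold) at its final sample. Windows whose
SBP **or** DBP target falls outside mean ± 1.96 SD of the dataset are
dropped (a zero-SD series keeps everything); the rule is applied exactly
once, per subject in the calibration regime and pooled in LOSO. Per-segment,
per-channel amplitude standardization (default on in the pipeline) removes
arbitrary sensor units.

Order of operations — filter at the native rate, then resample, then window
— is fixed for determinism; a regression test bounds the discrepancy versus
the resample-first order at 2% for in-band content.

## Model and training

Architecture details are in the README. Numerical choices: BatchNorm with
momentum 0.1 and eps 1e-5 placed conv → BN → ReLU; max-pool uses ceil-mode
lengths with −inf padding (so 625 → 209 → 70 → 24 → 8); GRU biases are
included (a config switch disables them); the initial GRU state is zero; the
attention score is a scalar per timestep with tanh activation; the output
head is purely affine (BP is unbounded regression). Weights are
Glorot-uniform from a seeded generator; everything is float64 numpy, and
training is bit-deterministic given the seed.

Optimization: Adam (β = 0.9/0.999), MSE over the (SBP, DBP) pair, inverse
time learning-rate decay `lr/(1 + decay·t)` per update, early stopping on
validation MSE with best-weight restoration. Defaults follow the reference
protocol (lr 1e-3, decay 1e-4, batch 512, ≤ 50 epochs, patience 10). Two
scaled-down choices apply at the package's demo problem size:

* **Target normalization** — `fit` optimizes in standardized target units
  (the affine calibration is stored on the model and undone at inference).
  With ~10² parameter updates available, raw-mmHg MSE (~10³–10⁴) would
  spend the whole budget reaching the target mean.
* **Demo optimization scale** — `demo_config` uses batch 32, lr 3e-3 and
  ≤ 30 epochs: at ~450 windows per subject, batch 512 would give one update
  per epoch. The paper-scale defaults remain `TrainConfig`'s defaults.

**Regimes.** Calibration-based: one model per subject, trained on that
subject's chronologically contiguous 70/10/20 split (contiguity limits
leakage between heavily overlapping windows; a `split_mode="random"` flag
gives the literal random split). Calibration-free: leave-one-subject-out —
one pooled model on the remaining subjects (87.5/12.5 train/val), tested on
every window of the held-out subject. Per-subject calibration is essential,
not cosmetic: subjects differ by their BP calibration line, and no
waveform feature can recover a subject's intercept, so a pooled
calibration model is bounded by between-subject variance (observed pooled
lag–SBP correlation 0.23 versus 0.85 within subject on the demo cohort).

## Baseline

R peaks: Pan–Tompkins stages (5–15 Hz band-pass, derivative, squaring,
150-ms moving-window integration, adaptive two-level thresholding with a
200-ms refractory period), refined to the local ECG maximum within ±50 ms;
all thresholds are relative, so detection is amplitude-scale-invariant.
J peak: BCG argmax in [R + 110 ms, R + 250 ms]. dPPG peak: maximum of the
PPG first derivative in (R, R + 0.6 s] — the window covers physiologic
transit times while preventing next-beat capture at ≥ 50 bpm. A cycle is
excluded when a window is truncated, an argmax pins to a window boundary,
or a peak falls below 0.25× the median per-cycle peak (automated,
scale-invariant stand-ins for manual false-positive review); the exclusion
fraction is reported. Features stay at native 1000 Hz timing resolution,
independent of the 125 Hz deep path. OLS (per target) regresses SBP and DBP
on (RRI, PTT, RJI); rank-deficient designs raise an error naming the
offending columns. In the pipeline the MLR is fitted pooled across subjects
on each subject's first 80% of cycles and tested on the last 20% — the
conventional single-calibration-line comparator — so part of its error on
multi-subject cohorts is between-subject offset.

## Evaluation conventions

Sample standard deviations (ddof = 1) throughout. The "MAE ± SD" convention
reports the SD of absolute errors; the AAMI SD is the SD of signed errors —
both are computed and named separately. Bland–Altman differences are
estimate − reference; LOA = mean ± 1.96 SD. AAMI and BHS threshold
comparisons are inclusive; the AAMI 85-subject population requirement is
surfaced as a flag rather than a failure. Attention timesteps map back to
input sections of 3⁴ = 81 samples (648 ms) each, the last section taking
the 58-sample (464 ms) remainder.

## Problem sizes

The demo cohort and acceptance runs use 3 subjects × 120 s at stride
0.25 s (~455 windows each), the reduced model (conv widths 8/16/32/64, GRU
hidden 16), and the demo optimization scale above; the full-width network
is instantiated and shape-audited but not trained at demo scale. These are
the package's chosen demonstration sizes; all components accept the
full-scale settings.

## Known limitations

* Synthetic-only evidence: the planted PTT→BP coupling is linear and
  stationary; real calibration drifts within minutes to hours.
* The generator's BP series has no dynamics beyond the slow sinusoid plus
  white per-beat noise; step changes and surges are untested.
* EDF input/output and plot rendering are not included; recordings travel
  as CSV with a JSON beat sidecar.
* The LOSO regime transfers nothing about a new subject; without
  per-subject calibration its error is dominated by intercept spread, and
  on the demo cohort it does not meet the AAMI criterion — consistent with
  the known difficulty of calibration-free estimation.
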