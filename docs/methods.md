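# Methods

This note documents the models, estimators, and design choices behind
pulsecheck, and what the synthetic-data results do and do not establish
about real wearable data.

## Data model and conventions

Records hold synchronously sampled channels (PPG in arbitrary units, ABP in
mmHg, ECG in mV) at a canonical internal rate of 125 Hz; readers
polyphase-resample other rates and retain the original rate. Sample indices
are 0-based and windows are half-open `[start, start+len)` in samples, so
overlap arithmetic is unambiguous: a segmentation with window `w` seconds
and overlap `v` strides by `w − v`, drops trailing partial windows, and a
2-s window at 125 Hz has exactly 250 samples — the scale at which the
multi-valued-mapping thresholds are defined.

Window labels are derived from co-recorded reference channels. The
window-level SBP is the mean of the ABP systolic-peak amplitudes inside the
window (per-beat maxima located with the same beat detector used on PPG);
there is no universal convention for reducing a pressure waveform to one
window value, so this choice is deliberately simple, linear in the
waveform (shifting ABP by +c shifts every label by exactly +c), and flagged
for sensitivity analysis. HR is 60 over the median inter-beat interval
(ECG R-peaks when an ECG channel exists, else PPG systolic peaks). Windows
whose label channel contains non-finite samples — transmission gaps are
common in ICU archives — are excluded from analyses and flagged, never
silently zeroed.

## Synthetic cohorts

The generator is a study-condition dial, not a physiological simulator.
Per patient it draws a baseline SBP (default uniform on 100–160 mmHg) and a
pulse-arrival delay (0.15–0.25 s); per record the SBP process at 2-s steps
is

```
SBP_w = baseline + AR1_w + rate_p · t_days + idio_p + latent_w
```

* `AR1_w`: slow fluctuation, coefficient 0.99 per step, innovation SD
  0.5 mmHg (stationary SD ≈ 3.5 mmHg) — within-record blood pressure
  changes little over minutes at rest.
* `latent_w` (ill mode only): i.i.d. N(0, latent_sd²) per window — the
  planted multi-valued component. It is i.i.d. per window rather than per
  beat so the planted fraction is analytically controllable.
* `rate_p · t_days`: per-patient drift, rate drawn N(0, drift_per_day²).
  The rate varies across patients because a common rate would move only the
  bias of calibrated errors, not their SD, making decay unobservable.
* `idio_p`: per-patient offset, N(0, patient_idiosyncrasy_sd²), modelling
  between-subject differences in the morphology-to-pressure relation.

Morphology — heart rate, reflected-wave delay, amplitude — is an
*invertible affine* function of the visible part `baseline + AR1` only
(HR maps 80–200 mmHg onto the configured hr_range, RWAT decreases with
pressure, amplitude increases mildly). Latent, drift and idiosyncrasy are
all PPG-invisible: they are exactly the blood-pressure variation that pulse
morphology cannot carry, which is what the conditioning, calibration and
leakage audits are designed to expose. With all three at zero (the
defaults), the waveform determines SBP and windows with equal
(hr, rwat, amp) have equal true SBP.

Beats are a two-Gaussian template: a systolic bump at 20% of the period
(width 7% of the period) plus a reflected bump delayed by RWAT at 35% of
the systolic height — the simplest morphology that exposes every
handcrafted feature. The ABP channel is the same shape scaled so its
systolic peaks equal true SBP (diastolic = SBP − 40); the ECG is a train of
6-ms Gaussian R-waves preceding each systolic peak by the patient's
pulse-arrival delay. Artifact injection adds, in order, sinusoidal baseline
wander (0.1–0.4 Hz), white noise, step amplitude changes at Poisson times,
and zeroed dropout gaps (0.5–2 s), all scaled to the signal's peak-to-peak
amplitude; default rates emulate a moderately corrupted wearable recording
(wander 10%, noise 5%, 0.5 dropouts and 0.5 jumps per minute).

What the generator does **not** emulate: realistic pulse morphology classes
(dicrotic notch variation, arrhythmia), sensor-specific transfer functions,
motion artifacts correlated with physiology, or genuinely nonlinear
pressure–morphology coupling. Passing tests on these cohorts therefore
establish that the *audit machinery* is correct (thresholds, estimators,
split logic, decay measurement) — not that any particular real dataset is
well- or ill-conditioned. On real data the same pipelines apply unchanged,
but their numbers inherit the reconstruction choices listed below.

## Multi-valued-mapping checker

Windows are min-max normalized per *record* (not per window): PPG units are
arbitrary, so a bounded scale is needed for a meaningful distance
threshold, but normalizing per window would destroy the within-record
amplitude information the comparison is supposed to preserve. For a pair,
the alignment lag maximizes the zero-mean circular cross-correlation within
±0.5 s (ties resolve toward the smallest |lag|; zero-variance windows get
lag 0); the pair distance is the L2 norm of the aligned difference over all
250 samples. The threshold geometry reads the input threshold 1.0 as an L2
norm, equivalently a mean-squared budget of 1.0²/250 = 4·10⁻³ per sample.
Circular shifting keeps the vector length fixed; the wrap-around edge
effect is accepted and is part of the distance definition.

A window is matched when at least one in-scope partner is within the input
threshold AND at least the output threshold apart in label (both
boundary-inclusive); the reported factor is the percentage of matched
windows (not matched pairs), with all labeled windows as the denominator in
both scopes. Intra- and inter-patient scopes partition the pair set.
Comparisons are only ever within one dataset, never across datasets with
different sensors. The O(n²) scan carries an exact pre-screen — circular
shifts preserve norms, so `| ‖x_i‖ − ‖x_j‖ |` lower-bounds the aligned
distance and pairs exceeding the threshold are skipped without aligning —
plus a label-gap screen; both are provably result-preserving and are
verified against the exhaustive double loop in tests.

## Mutual information and Info-Fraction

Differential entropy of a continuous target is scale-dependent and can be
negative, so "MI over entropy" is only a meaningful fraction if both
numerator and denominator refer to the same discretization. The default
pipeline therefore quantizes the target at sensor resolution (floor
division; 1 mmHg for SBP, 1 bpm for HR, 0.01 s for RWAT), takes the plug-in
Shannon entropy of the quantized target as the denominator, and estimates
the numerator with the Ross nearest-neighbor estimator between the
continuous feature block and the quantized target (classes with a single
member are excluded; Chebyshev metric). Pure-continuous KSG (algorithm 1:
joint Chebyshev balls at the k-th neighbor distance, strict marginal
counts, ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩) is retained for
continuous–continuous use and as an option for the ratio.

Defaults: k = 3 (common k-NN MI practice), per-column standardization, and
seeded tie-breaking jitter of 10⁻¹⁰ of each column's SD (the estimators
assume continuous distributions without duplicate coordinates). Estimates
are clamped at 0 and the ratio at [0, 1], with clamping logged. Known
limitations: k-NN MI is biased downward in high dimensions at moderate n —
with 20-dimensional autoencoder embeddings of phase-unaligned 2-s windows,
the HR Info-Fraction reads ≈ 0.5–0.7 even though the embedding determines
HR; aligning windows to beat onsets removes the phase nuisance and the
estimate rises above 0.9. Feature tables fed to the estimator should be
low-dimensional or phase-normalized for this reason.

## Preprocessing and filters

The band-pass is a zero-phase 4th-order Butterworth (0.5–16 Hz) applied
forward–backward: only the band edges are conventional, and zero phase
matters because beat-relative timing is a feature. The autocorrelation
quality score removes the window mean and takes the maximum, over lags
0.33–2.0 s (pulse periods of 30–180 bpm), of the correlation between the
overlapping segments `x[:-l]` and `x[l:]`, normalized by the segment
energies. Normalizing by overlap energy (rather than the biased full-window
convention) keeps a perfectly periodic pulse near 1 regardless of how many
periods fit the window; lags beyond half the window are skipped because a
few-sample overlap makes the correlation estimate degenerate. Zero-variance
windows score 0. The SBP range filter uses closed intervals (the
literature's ranges are stated as closed); unlabeled windows are counted
separately from rejected ones. Every filter reports retention, because
retention is the audited quantity.

## Beat detection and features

PPG systolic peaks: local maxima above a rolling 75th-percentile threshold
(2-s neighborhood), 0.33-s minimum separation, then secondary-wave
rejection — each peak must reach half of the locally (±0.75 s) normalized
amplitude range, which discards reflected/dicrotic bumps without any
absolute amplitude assumption. ECG R-peaks: threshold on the squared first
difference at a fraction of its upper quantile with a 0.33-s refractory,
refined to the local ECG maximum (a deliberately minimal Pan–Tompkins).
Inter-beat intervals outside 0.27–2.0 s are excluded from interval
statistics (normal-to-normal cleaning).

SDNN is the population SD of NN intervals; spans of ≥ 60 s are subdivided
into 60-s periods and per-period SDs averaged (the subdivision length is a
documented choice; short windows are a single period). The quality score
averages up to three clamped components — autocorrelation self-similarity,
fraction of samples outside constant runs ≥ 80 ms (dropout/clipping), and
mean pairwise correlation of per-beat templates resampled to a common
length — omitting components whose preconditions fail; the composition is a
reconstruction of proprietary wearable quality heuristics with documented
weights (equal). The systolic ramp is (peak − foot)/(rise time) per beat
(foot = minimum between consecutive peaks), normalized by multiplying with
the beat duration; the feature is the mean over beats. rPAT is the median
delay from each PPG systolic peak to its nearest preceding R-peak within
0.6 s. HR features are computed from the PPG pulse train (matching archives
where PPG–ECG time alignment is untrustworthy); the ECG is used only for
arrival-time features, and the source channel is recorded per row.

The autoencoder is a 250–128–20–128–250 ReLU MLP trained with Adam
(step 10⁻³, minibatch 128) on per-window min-max-normalized inputs; only
depth, bottleneck width, activation, step size, and the stop rule
(epoch reconstruction MSE < 0.1, epoch cap 200 with a logged warning) are
structural commitments — the hidden width 128 is this package's choice.
Encoding is a deterministic forward pass to the bottleneck.

## Splits, leakage, calibration, grading

Splits operate on labeled windows with provenance. `no_overlap` partitions
patient ids 80/20 (simple random, seeded; no stratification),
`domain_overlap` partitions record ids (patients may straddle),
`data_overlap` splits windows at random after overlapping 10-s/5-s windows
have been generated — the order matters: windowing before splitting is
precisely what leaks raw samples. The leakage detector counts shared
patients, shared records, and train/test window pairs from the same record
whose half-open sample intervals intersect.

Naive calibration predicts the mean ground truth of a unit's first three
windows (the predictor is ignored); offset calibration adds
truth − prediction of the first window to all later predictions;
calibration windows are excluded from evaluation. The calibration unit is
the record by default (matching short-record evaluations) or the patient,
where the constant from the head of the first record applies across all
later records — the scope at which decay over days is observable; the decay
curve bins errors by elapsed time since calibration in 1-day bins
(configurable; no standard binning exists). Error SD is the population SD
of pred − truth. AAMI limits (|bias| ≤ 5, SD ≤ 8 mmHg) are inclusive; BHS
grades from cumulative |error| fractions at 5/10/15 mmHg (A: 60/85/95, B:
50/75/90, C: 40/65/85, else D).

Two plumbing predictors exist solely to exercise the audit machinery and
carry no accuracy claims: a ridge regression on handcrafted features
(α = 1), and a 1-nearest-window predictor on per-window normalized samples.
The ranking experiment across split modes uses the nearest-window
memorizer: leakage inflates accuracy through memorization, and a penalized
global linear model is nearly incapable of exploiting shared identity or
shared samples, so ridge alone would understate the effect that
over-parameterized networks exhibit.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; identical seeds reproduce cohorts,
splits, and estimates bit for bit. Zero-variance windows: quality 0,
alignment lag 0, correlation 0. Constant targets: entropy 0, MI 0, the
Info-Fraction undefined and flagged. Empty beat sets propagate as missing
features with a flag, never as zeros. Records shorter than one window
segment to an empty list with a logged warning rather than an error.
Distance and correlation ties resolve deterministically (first maximum in a
smallest-|lag|-first order).

## Problem sizes

Test and acceptance runs use cohorts of 2–10 patients, 1–11 records of
60–360 s, up to ~4 000 windows per analysis, and n = 4000 samples for
estimator-accuracy checks — sizes at which every stated tolerance
(Gaussian MI within 0.05 nats, planted fraction within 3 points, HR within
1 bpm, rPAT within 10 ms) has comfortable statistical power while a full
run of the suite plus acceptance script completes in about a minute.
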