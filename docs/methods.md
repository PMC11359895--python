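# Methods

This note documents the models, parameter choices and numerical conventions
behind the watchwalk pipeline, and what the synthetic validation does and
does not demonstrate.

## Signal model and conditioning

The input is wrist acceleration in g, nominally 100 Hz, columns x/y/z.
Inputs at other rates are linearly resampled to the configured rate so the
window and feature semantics stay fixed. Timestamp gaps larger than 1.5
sample intervals are treated as recording breaks; filtering and windowing
restart after a break and windows never span one.

The per-sample Euclidean norm is band-pass filtered with a 5th-order
Butterworth (0.25–2.5 Hz pass band — the locomotor band at wrist level) in
second-order sections, applied forward–backward (`sosfiltfilt`). Zero-phase
filtering was chosen because step-event *timing* feeds cadence and
variability downstream; a causal filter would bias step times by the group
delay. The effective amplitude response of the zero-phase filter is the
squared magnitude of the underlying filter; tests compare it against the
closed-form analog Butterworth band-pass response (relative at 1 Hz, where
bilinear warping is negligible; absolute at 10 Hz, where both responses are
below 1e-6 of the input).

Windows are non-overlapping 4-s blocks (400 samples); the trailing remainder
of each contiguous segment is discarded.

## Features (version `ww-54-v1`)

Each window yields exactly 54 features; the order is fixed and versioned,
and a model refuses to score a frame from a different feature version. The
set spans: band-passed-norm time-domain statistics (mean, SD, median, IQR,
min, max, RMS, skewness, kurtosis, signal-magnitude area, zero crossings,
MAD, 5/25/75/95th percentiles); spectral descriptors (dominant frequency and
its power fraction, spectral entropy, spectral centroid, band powers in
0.25–0.75 / 0.75–1.25 / 1.25–1.75 / 1.75–2.5 Hz); autocorrelation step and
stride peak coefficients and lags; raw per-axis mean/SD/range; band-passed
per-axis SDs and pairwise correlations (computed on the movement band, where
gravity no longer dominates); jerk mean/SD; crude-norm summaries (mean, SD,
median, IQR, min, max); and gravity-subtracted (ENMO-style,
max(‖a‖ − 1 g, 0)) mean, median and IQR. Dispersion features are exactly
zero on constant input; correlation- and autocorrelation-type features are
amplitude-invariant, amplitude-type features scale linearly with a global
gain.

The published method fixes only the dimensionality (54) and the kernel
coefficient γ = 1/54; the identity of the original 54 features is not
recoverable, so this set is a re-design of the same dimensionality and
trained weights are not expected to transfer between implementations.

## Two-stage classification

Both stages are RBF-kernel SVMs on z-scaled features (the scaler is fitted
on training folds only; a fixed γ is only meaningful on commensurate
scales). Stage 1 separates six classes with per-class weights
[50, 25, 10, 5, 5, 5] (walking classes up-weighted); stage 2 runs only on
windows labelled "other complex walking" with uniform weights, resolving
five hand positions. The multiclass reduction is libsvm's native one-vs-one
with the class weights applied per binary problem. The cost parameter is
C = 1 (library default, recorded in model metadata).

Cross-validation is participant-level 10-fold: participants are sorted,
shuffled by a seeded RNG and dealt round-robin into folds, so no
participant's windows are split across folds and the assignment is invariant
to window order. With fewer than 10 participants this degenerates to
leave-one-participant-out. Training rows are internally sorted by
(participant, window start time), which makes fits and out-of-fold
predictions invariant to the order frames are supplied in.

## Walking bouts and gap bridging

A window counts as walking when stage 1 says arm-swing or complex walking.
The three bridging criteria are read as: gap ≤ 60 s; gap ≤ min(preceding,
following run duration); gap ≤ max(preceding, following)/5 — the only
reading under which the second and third criteria are non-redundant for
unequal neighbours. Bridging sweeps left-to-right and repeats to a fixpoint,
because a merge lengthens its neighbours and can enable further bridging;
the fixed order makes the result deterministic. Bridged gap time counts
toward bout duration (and hence toward the longest walk and the
cumulative-exposure percentages of walks ≥ 8 s / ≥ 60 s) but contributes no
steps. The rule is isolated in `gap_bridgeable` so an alternative reading
can be swapped and re-tested in one place.

## Step detection and gait-quality metrics

Within each walking window, candidate peaks of the band-passed norm need a
minimum spacing of 0.25 s and prominence ≥ 0.25 × window RMS. The
autocorrelation cross-check works on the unbiased, lag-0-normalized
autocorrelation: the step period is the *first dominant* peak in the
0.25–1.0 s lag range (smallest lag reaching both the 0.25 coefficient floor
and half the strongest in-range peak). Taking the first dominant rather than
the global maximum matters: when gait has a pronounced stride-level
asymmetry, the stride-period peak can exceed the step-period peak and the
global maximum would halve the cadence. Candidate peaks are then snapped to
a period-spaced comb (every candidate is tried as the comb anchor; the comb
matching the most, then the strongest, peaks wins), which skips harmonic
sub-peaks between steps; finally the median spacing of the kept peaks must
agree with the autocorrelation period within ±20% or the window reports no
steps. Detection stays per-window, but each window borrows 0.5 s of context
from contiguous neighbours so a peak on a window boundary is neither lost
nor double-counted. Aperiodic (white-noise-like) windows are rejected by the
absence of a credible autocorrelation peak — in simulation the false-peak
rate on iid noise windows was 0/3000.

Steps are regrouped into 8-step episodes (7 intervals; episode duration runs
from first to last step, cadence = 7·60/duration steps/min). Sequences are
broken where an interval exceeds 1.8 × the bout's median interval — an
evidently missed step means the steps are not consecutive, and a single such
gap would otherwise dominate the episode SD. Daily cadence is the median
(and IQR) over episodes; daily step-time variability is the 95th percentile
of episode SDs. All percentiles in the package use one quantile rule: linear
interpolation between order statistics (`numpy` "linear").

Step and stride regularity are the autocorrelation coefficients at the step
peak and at the peak nearest double its lag (±25%); both lie in [−1, 1] and
are amplitude-invariant. Daily values aggregate by the plain mean over
walking windows with a defined pair (the aggregation policy is a named
choice; median pooling would also be defensible).

The corrective step count adds (mean ground-truth steps per
unspecified-arms-walking window, estimated during training and persisted in
model metadata) × (number of such windows in the day). How the original
corrective factor was derived is not recoverable; this per-window-rate
estimator is a documented stand-in with the same information source.

## Walking speed

Only arm-swing windows with at least two detected steps are scored; the
eight predictors are, in fixed order: sex code (0 female / 1 male), body
height (cm), median and IQR of the gravity-subtracted magnitude (g), mean
crude magnitude (g), mean step time (s), and the Pearson correlations of the
band-passed x–y and x–z axes. The regressor is an RBF-kernel SVR with
γ = 1/8 (mirroring the 1/n_features convention), C = 1 and ε = 0.01 m/s
(1 cm/s precision target), on z-scaled predictors; folds are
participant-level as above. Daily usual and maximal speeds are the median
and 95th percentile of the day's per-window predictions, reported in cm/s in
the biomarker table. A known limitation of kernel regression under
participant-level folds: the fastest/slowest subject in a cohort is scored
partly by extrapolation and shrinks toward the training mean.

## Sleep

A simplified variant of the arm-angle family of sleep detectors: the
elevation angle atan(z/√(x²+y²)) is computed on 5-s epoch medians of the raw
axes; runs where the successive-epoch angle change stays below 5° for at
least 5 min are sustained-inactivity blocks; blocks separated by < 60 min
are joined; the longest joined block within the noon-to-noon day slice is
the sleep period (duration = span, bedtime = onset clock time). Days are
noon-to-noon precisely so a night is never split at midnight. Deliberately
omitted relative to the full published algorithm: diary anchoring,
multi-night harmonisation and nap handling. Bedtimes pool across days by the
circular mean on the 24-h clock. The estimate is flagged missing when the
slice holds under 12 h of data or no qualifying block exists.

## Daily summary, wear time and normative machinery

Hand-position percentages are computed over walking windows (arm swing plus
the five stage-2 classes sum to 100%); "% static" = texting + phone call and
"% adaptive" = pockets + shoulder bag + briefcase by construction. A day
with no walking reports the gait fields as missing with reason codes — never
as zeros.

Non-wear detection: 60-min blocks slid in 15-min tiles; a block is non-wear
when all three axes have SD < 13 mg over the block. Wear hours = covered
time − non-wear time. "Complete day" is operationalized as ≥ 23 wear-hours
(the source convention for "complete" is not recoverable; the threshold sits
in the config). Inclusion criteria: ≥ 5 complete days (full) or ≥ 3 days
with ≥ 12 wear-hours (relaxed).

For normative tables, days pool to one row per subject — mean for
approximately normal markers, median for the markers conventionally reported
as median/IQR (longest walk, % walk ≥ 60 s, hand-position percentages); the
skew classification is fixed in code, not re-estimated. Percentile grids
(5/10/25/50/75/90/95) stratify by sex × age group over edges
[45, 55, 65, 75, 80); empty strata report n = 0 with missing percentiles.
Z-score profiles standardize against a reference cohort's mean and SD, with
the sign flipped for lower-is-better markers (step-time variability) so
positive always means better; bedtime is not scored (clock time has no
better/worse direction).

## Reliability metrics

ICC(2,k) is computed from the explicit two-way ANOVA mean squares
(MSR between subjects, MSC between days, MSE residual):
ICC(2,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n). Rows with missing days are
dropped (absolute-agreement formulas assume a complete layout; the retained
count is reported). The 95% CI uses the F-distribution bounds for the
single-measurement form transformed to the average-measures scale
(Spearman–Brown); the implementation agrees with pingouin's ICC(A,k) row to
numerical precision and is cross-checked against it in the tests. MAPE is
the mean (and SD) of |pred − truth|/|truth| × 100 and refuses zero truth
entries by index. Group contrasts report descriptive summaries; the omnibus
p-values are delegated verbatim to scipy's t-test/ANOVA or
Mann–Whitney/Kruskal–Wallis.

## The synthetic-data generator

The generator emulates, with complete ground truth, the two data settings
the method needs: a laboratory development protocol (each of six hand
positions at slow/usual/fast paces — 0.7/1.0/1.3 × the subject's usual
speed, two walkway passes for arm swing — plus running, unspecified arm
activities and stationary blocks) and multi-day free living (night sleep
around 23:00–07:00, daytime rest and log-normal walking bouts totalling
~75 min/day, hand positions dominated by arm swing).

Generative model: walking phase advances 2π per step; step times follow the
scheduled cadence with Gaussian *interval* jitter (so the SD of consecutive
intervals equals the scheduled jitter; free-living default 40 ms, laboratory
15 ms). The gait impact component acts along the instantaneous gravity
direction — the norm oscillation amplitude is therefore posture-independent
— while class-specific transverse components (distinct amplitude, axis mix,
phase offsets, harmonic and stride-asymmetry weights per hand position) give
the classifier separable signatures and the axis-correlation features their
information. True speed enters through two documented monotone couplings:
amplitude × (0.4 + 0.6·v) and cadence = 60 + 35·v (v in m/s); subject usual
speed depends on sex (+0.08 m/s for men), age (−0.004 m/s per year past 60)
and height (+0.004 m/s per cm above the sex mean), with configurable
between-subject (0.10 m/s) and between-day (0.03 m/s) SDs. Waking posture
wanders as a mean-reverting AR(1) gravity direction (~8° per 5 s); sleep
holds a stable tilted orientation (~0.3°); "nonwear" renders a nearly dead
channel. Worn-but-still tissue noise (15–18 mg) keeps genuine wear above the
13 mg non-wear threshold. A `noise_scale` multiplier scales every stochastic
component; 0 gives the noise-free limit used by the step-recovery checks.
Ground-truth step counts are fixed by cadence × duration and invariant to
the noise seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: biomechanically realistic gait (the waveform is a
low-order sinusoid model), terrain and environment effects, device
calibration error, genuinely ambiguous activities (cycling, driving),
population-realistic activity diversity, or real inter-feature noise
structure. Classification accuracies near 99% on synthetic cohorts reflect
the scripted separability of the classes, not expected field performance;
conversely, rule-based components (bridging, episodes, percentiles, ICC,
wear time) are exercised exactly as they would run on real data.

## Problem sizes and numerical conventions

The test suite and acceptance script use: 20-subject development cohorts
(~290 windows each) for classifier and speed recovery; 60-s single-activity
recordings for step/cadence recovery (noise-free); 100 × 7 two-way cohorts,
averaged over 20 replicates per target, for ICC recovery (a single cohort's
estimator SD at θ = 0.5 is ≈ 0.08, so single-draw checks against ±0.05
would measure sampling noise, not bias); and one subject × 1–2 full 24-h
days for end-to-end determinism and biomarker recovery. All randomness flows
from explicit seeds; identical inputs and seeds give bit-identical outputs,
including the daily biomarker table.

Degenerate inputs are conventions, not errors: constant windows have zero
dispersion features and no steps; days without walking report missing gait
markers; empty strata report n = 0; the exposure percentages are missing
(not 0) when there is no walking time. Ties and peak ambiguities are broken
deterministically (first dominant peak; smallest lag; left-to-right
bridging).
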