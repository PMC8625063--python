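# Methods

This note documents the models and numerical choices behind `shankpose`:
what each stage computes, which knobs matter, what the synthetic benchmark
does and does not emulate, and where the design was genuinely open.

## Problem setting

A thigh-worn event-based activity monitor supplies ground-truth posture
labels as variable-duration events over the eight codes *sitting, standing,
stepping, cycling, primary lying, secondary lying, non-wear, travelling*.
A second sensor on the shank records tri-axial acceleration at 20 Hz in
units of g.  The task is to learn to predict the (merged) posture from the
shank signal alone, so that a monitor embedded in a prosthetic shank can
replace the thigh sensor.

## Windowing

Event codes are first merged to the four modelling classes (cycling →
stepping, both lying variants → lying) and non-wear/travelling intervals
are deleted; adjacent events that end up with the same label are coalesced,
since window purity is a property of the label, not of event identity.
Candidate windows of length L ∈ {5, 15, 30, 60, 120, 180} s slide on a grid
anchored at the recording origin with step L·(1 − overlap), overlap 0.5 by
default.  A candidate is kept iff its whole interval lies inside a single
merged event.  Anchoring to the recording origin (rather than re-anchoring
at each event start) reflects a single sliding pass over the data; the
purity filter then handles boundaries.  The two anchoring conventions can
differ by at most one window per event.  When subjects contribute unequal
amounts of data, both inputs can be clipped to the first *n* days
(default 3) so each subject contributes equally.

Floating-point details: window containment is tested with a 1 ns tolerance,
and a stream may exceed the recording span by up to one sample period,
because recordings are quantized to the sample grid.  Sample slices are
copied, never aliased.

## Features

Each axis is filtered with a 4th-order low-pass Butterworth at 5 Hz,
applied forward–backward (`filtfilt`).  Zero-phase filtering doubles the
effective order but avoids the group delay that would otherwise shift
signal content relative to the window; it is the standard choice in offline
movement analysis.  VM = √(x² + y² + z²) is formed from the *filtered*
axes.  For each signal s ∈ {X, Y, Z, VM}, 25 features:

| feature | definition |
|---|---|
| mean, max, min | plain |
| std | population standard deviation (ddof = 0) |
| mean_abs_dev | mean |s − mean(s)| (about the mean, not the median) |
| sma | mean |s| — signal magnitude area read per signal |
| energy | mean s² — normalized by sample count so windows of different lengths are comparable |
| iqr | 75th − 25th percentile (linear interpolation) |
| autocorr_lag1 | Pearson correlation of (s_t, s_{t+1}); defined as 0 for numerically constant signals (tolerance 1e−9 relative to signal amplitude, needed because zero-phase filtering leaves ~1e−15 ripple on constants) |
| peak_power_1..6, peak_freq_1..6 | the 6 largest strict local maxima of the periodogram, ranked by power (ties broken toward lower frequency); missing peaks padded with (0, 0) |
| band_power_1..4 | periodogram power summed over (0, 2.5], (2.5, 5], (5, 7.5], (7.5, 10] Hz |

The periodogram is a single unwindowed transform of the mean-removed,
filtered signal, normalized so its total power over (0, Nyquist] equals the
population variance; the four band powers therefore sum exactly to that
total (Parseval).  No tapering or segment averaging is used — the simplest
estimator keeps every feature verifiable against a direct-summation oracle.
The DC and Nyquist bins can never be peaks.  Reading "six peak powers plus
their six frequencies" is the only interpretation that makes the per-signal
count 25 and the total exactly 100; the band edges are an equal partition
of the Nyquist range, the neutral choice where none is prescribed.

One consequence of placing a band edge exactly at the −3 dB cutoff: after
zero-phase order-4 filtering, white noise retains ≈3% of its power above
5 Hz in expectation (∫|H|⁴ above cutoff), so the above-cutoff band powers
are small but not negligible; the test suite asserts < 5% against the
unfiltered 50%.

## Selection

Pipeline order: min–max scale each feature to [0, 1] (constant columns map
to 0), drop columns with scaled variance < 0.01, then drop correlated
columns with |Pearson r| > 0.8 by a greedy left-to-right scan in the fixed
feature-registry order — a column is removed iff it correlates too strongly
with an *earlier retained* column, so the survivor of a correlated pair is
deterministic.  The fitted minima/maxima and drop lists form a
`SelectionReport` replayable on held-out data (out-of-range values are
clipped to [0, 1]).  On the default synthetic benchmark this retains ~30 of
the 100 features.

Two leakage modes are exposed because the described procedure fits the
selection on the full dataset before cross-validation: the default
reproduces that behaviour faithfully; `leakage_safe=True` refits scaling
and pruning inside every training fold (and on the tuning split's training
portion).  On separable synthetic data the two agree to Monte-Carlo noise.

## Modelling and evaluation

Classes are balanced once per windowed dataset by seeded downsampling to
the minority count.  Eight families are supported with small fixed grids
(the grids are a package choice — no canonical grids exist for this
problem): KNN (k ∈ {1,3,5,9,15}), LDA (—), SVM (C ∈ {0.1,1,10} ×
{rbf, linear}), RF/ET (100 trees, depth ∈ {∞, 10}), LR (C ∈ {0.1,1,10}),
NB (—), QDA (reg ∈ {0, 0.01, 0.1}).  Tuning draws a stratified 10% subset,
splits it 80/20 (stratified), scores every grid point by weighted F on the
20% portion and keeps the first best.  The tuning subset is drawn from the
same pool used for cross-validation (the faithful reading of the
procedure); the subset must give every class ≥ 2 members or an error
advises a larger fraction.

Evaluation is stratified k-fold cross-validation (k = 10).  Per-class
precision, recall and F are averaged across folds; the weighted F is the
support-weighted mean of the fold-averaged class Fs (so the reported value
is exactly consistent with its parts); the confusion matrix is the
row-normalized mean of per-fold count matrices, rows = true class, rows sum
to 100%.  F is defined as 0 when precision + recall = 0, and a true class
absent from an input yields an undefined (NaN) confusion row rather than a
silent zero.  All randomness derives from one master seed via
`SeedSequence([master, length_index, family_index, stage])`, making every
report byte-reproducible.

## Synthetic benchmark

Behaviour: a semi-Markov chain — per-posture log-normal bout durations
(parameterized by arithmetic mean and log-σ) and a transition weight table
with no self-transitions.  Defaults give long sitting/lying bouts
(20 min / 1 h means), shorter standing/stepping bouts (2 min / 90 s), and
occasional cycling, non-wear and travelling so the label-merging rules are
exercised.  Signal: each posture has a mean shank attitude (tilt from
vertical, azimuth for lying), giving gravity
(sin θ cos φ, sin θ sin φ, cos θ) g in the sensor frame (z longitudinal,
x anteroposterior), plus two slow (0.01–0.08 Hz) sinusoidal drift
components per bout, Gaussian micro-movement noise, and — for stepping and
cycling — a cadence fundamental (1.8 Hz / 1.2 Hz) with a second harmonic on
the longitudinal axis and a phase-shifted anteroposterior component.
Static postures therefore have VM ≈ 1 g, and every sample's label is known
by construction.

Sitting and standing are deliberately the closest pair (both near-vertical
shank): the default conditions separate them by a 22° tilt offset plus
differing noise, which a random forest resolves essentially perfectly —
the separable-limit check.  The *reduced tilt gap* variant shrinks the mean
offset to 2° around a 9° tilt with equal noise, and additionally draws a
per-bout sitting tilt mode from {−5°, 0°, +5°} (different seated leg
placements), so the sitting attitude distribution is multimodal and
straddles standing.  This reproduces two qualitative phenomena of the real
problem: the dominant confusion is sitting ↔ standing, and ensemble
classifiers beat Gaussian naive Bayes (which is near-optimal when classes
differ only by a clean mean shift, but cannot represent multimodal
classes).  Because individual benchmark replicates of this hard variant are
noisy (a few hundred windows per class after balancing), the ranking is
asserted on the mean over three replicates.

What the simulator does **not** emulate: biomechanically realistic gait
(impact transients, asymmetry), prosthesis-specific artefacts, sensor bias
and calibration error, and label noise from the reference monitor
(reported ≈90% accurate in amputees).  Passing the synthetic checks
therefore demonstrates the pipeline's correctness and its qualitative
behaviour, not field accuracy on real amputee data.

## Problem sizes and defaults

The benchmark default is 5 subjects × 6 h at 20 Hz (≈13,000 pure 15 s
windows, ≈2,000 after balancing), which the package treats as its standard
desk-scale study; the original deployment scale (15 participants × 3 days)
is reachable with the same code by raising `duration_s` and `n_subjects`.
All stage seeds stay below 2³¹ so they are valid for every downstream
library.

## Known limitations

- The feature set is fixed; no wavelet, adjacent-window or learned features.
- Windows containing posture transitions are discarded, so the evaluation
  covers pure-posture behaviour only.
- Balancing by downsampling discards data; no oversampling option.
- The 10% tuning subset is not held out of cross-validation in the default
  (faithful) mode, which slightly flatters all families equally.
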