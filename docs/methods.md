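# Methods

This note records the models, numerical choices and default parameters
behind `gaitrisk`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and preprocessing

A recording is a set of synchronized channels against one timestamp
vector: raw device-frame acceleration (m/s²), gravity-removed body-frame
linear acceleration (anterior-posterior, medio-lateral, vertical; AP
positive forward, ML positive rightward, vertical positive upward),
angular velocity (rad/s), and pelvis orientation angles tilt, obliquity
and rotation (degrees, about the ML, AP and vertical axes). Sign
conventions are a package choice; the simulator and detectors share them.

Preprocessing is linear re-interpolation to a uniform 50 Hz grid (the new
grid starts at the first input timestamp and never extends past the last)
followed by a fourth-order zero-lag Butterworth low-pass at 4 Hz. The
filter is applied forward and backward (`filtfilt`, reflective padding of
3·(order+1) samples), so phase is exactly zero and the effective gain is
|H(f)|². It is applied to the linear-acceleration, gyroscope and
orientation channels; raw device-frame acceleration is kept unfiltered as
provenance.

**Filter discretization.** The digital coefficients come from
impulse-invariant discretization of the analog Butterworth prototype,
normalized to unit DC gain, rather than the more common bilinear
transform. Rationale: the Butterworth filter is *defined* by its magnitude
response |H(f)| = (1+(f/f_c)^(2n))^(−1/2), and at 50 Hz sampling the
bilinear transform's frequency warping distorts that response badly in the
stop band (gain at 8 Hz ≈ 40% below the Butterworth value). Impulse
invariance preserves the defining magnitude to <0.5% over the band of
interest. The trade-off — response aliasing — is negligible for a 4 Hz
cutoff at 50 Hz sampling, and the cutoff is restricted to below Nyquist.

## Foot-strike detection

**Rule-based labeller.** Foot strikes are AP local maxima immediately
followed by a vertical local maximum. Implementation: AP peaks with
prominence ≥ 0.5·SD(AP), separated by at least the locking period, are
kept when a vertical peak occurs within 0.1 s after them. Flat signals
yield an empty event list.

**Adaptive locking period.** A per-trial refractory interval, derived from
the first 5 s of filtered vertical acceleration: the step period is the
lag of the first autocorrelation peak that reaches ≥ 70% of the strongest
peak, searched over 0.25–1.2 s; the locking period is half that period
(floored), clamped to [10, 35] frames. Taking the *first* prominent peak
instead of the global maximum matters for asymmetric gait: at the stride
lag every step's pulse aligns, so the stride peak dominates, and locking
on it would suppress alternate strikes. A signal with no peak above 0.25
normalized autocorrelation (e.g. noise) falls back to the lower clamp.

**Trainable detector.** A windowed MLP sequence labeller: each frame is
featurized as the standardized values of the nine movement channels
(linear acceleration, gyroscope, orientation) over a ±7-frame window
(135 inputs), classified by a single-hidden-layer MLP (64 units,
scikit-learn `MLPClassifier`, ≤200 iterations, fixed random state).
Strike frames are ~4% of all frames, so training keeps every positive
frame, all negatives within the window radius of a positive (the hard
cases), and a seeded 4:1 random subsample of the remaining negatives.
At inference the predicted strike probability is decoded by local-maximum
picking (threshold 0.5, minimum spacing = window radius), which keeps raw
predictions near one frame per strike. Training sets whose labels contain
a single class produce a constant predictor. Training and inference are
deterministic given the seed.

**Post-processing.** (1) Each maximal run of consecutive positive labels
collapses to the frame of maximum AP acceleration within the run (earliest
frame on ties). (2) Missed-step insertion: a gap between consecutive
events longer than 1.5× the preceding step duration (the trial-median
interval for the first gap, which has no preceding step) is searched for
the highest AP *local peak*, with the search range shrunk by half the
locking period at each end; passes repeat until no qualifying gap gains an
event (bounded at 20 passes). Requiring a genuine local peak, not a bare
argmax, is what terminates the loop: a gap that keeps qualifying but
contains no further peak is left alone. Fewer than three events pass
through unchanged. (3) Sides are assigned by alternation, seeded by the
sign of ML acceleration at the first strike (positive → right under the
package's sign convention); a flat ML channel leaves sides unknown.

**Metrics.** Frame-wise accuracy/sensitivity/specificity over the binary
per-frame labels; an optional tolerance mode counts a prediction within
±2 frames (±0.04 s) of a true strike as correct, the usual allowance for
one-frame timing jitter.

## Step features

Steps are the intervals between consecutive strikes of either foot; a
stride spans consecutive same-side strikes. Steps whose window contains a
pelvis rotation rate above 45 °/s (derivative of the rotation angle) are
flagged as turning and excluded by default — the peak rate is used rather
than the window mean so that any step overlapping a turn is excluded.

Per step, 62 features in a fixed registry order:

* **Temporal (5).** Step time = window duration, attributed to the
  starting side; the opposite side's time comes from the previous window
  (the next one for the first step). Stride time = sum of the two.
  Cadence = 60/step-time, kept per-step so its aggregates are step-based
  like every other feature. Symmetry index = |t_R − t_L| / (½(t_R+t_L)) ×
  100 (0 = perfect symmetry, 200 = maximal). Unknown sides fall back to
  alternating pseudo-sides with a warning.
* **Descriptive (27).** Min/max/mean of ML, AP and vertical acceleration;
  mean and range of tilt, rotation, obliquity; SD (population, within the
  window) and RMS of all six channels.
* **Spectral (30).** Per channel, the single-sided FFT magnitude spectrum
  of the mean-removed window, zero-padded to 256 points: 25th percentile
  ("quartile FFT"), maximum, SD, peak distinction = (max − mean)/max (0
  for an all-zero spectrum), and REOH = even-harmonic power / total
  harmonic power at integer multiples of the trial-level step frequency
  up to Nyquist, each harmonic read from its nearest bin (0 when no
  harmonic carries power; bounded in [0,1]). The quartile, peak-distinction
  and REOH formulas and the 256-point padding are package definitions —
  these feature names circulate in the gait literature without canonical
  formulas.

The participant vector is min, max, mean and sample SD (n−1) of each
feature over all included steps, ordered feature-major (f₁_min, f₁_max,
f₁_mean, f₁_sd, f₂_min, …) for 62 × 4 = 248 values; it requires at least
two steps.

## Classification

CFS scores a subset S of k features by merit(S) = k·r̄_cf / √(k +
k(k−1)·r̄_ff), with r̄_cf the mean |Pearson| feature–class correlation
(point-biserial against the 0/1 label) and r̄_ff the mean |Pearson|
pairwise feature–feature correlation. Pearson rather than discretized
symmetric uncertainty is a package choice: the features are continuous
and the label binary, so point-biserial correlation is the natural
continuous analogue. Zero-variance features contribute zero correlation
(warned). The search is best-first forward: start from the single best
feature, repeatedly expand the open subset of highest merit by one
feature, stop after 5 consecutive expansions that fail to improve the
best merit; ties break by registry order, so selection is deterministic.

The classifier is a random forest (100 trees, √d candidate features per
split, no depth cap, majority vote, fixed seed) evaluated by
leave-one-out cross-validation. CFS runs inside each fold on the n−1
training members only; the held-out member never influences selection or
training (verified by test). The confusion matrix accumulates the n
held-out predictions; fall risk is the positive class. Accuracy,
sensitivity and specificity are computed with exact rational arithmetic
and reported to one decimal as percentages.

## Synthetic gait generator

The simulator emulates what the pipeline needs from a 6MWT recording, not
amputee biomechanics. Each walk: strikes alternate sides with intervals
t_R = T·2r/(1+r), t_L = T·2/(1+r) (T = 60/cadence, r = right/left
step-time ratio), snapped to the sampling grid so ground-truth frames are
exact; each strike contributes a Gaussian AP pulse (σ = 50 ms) and a
vertical pulse 40 ms later — the peak ordering the labelling rule relies
on; ML is a stride-frequency sinusoid phased positive at right strikes;
tilt/obliquity oscillate at step/stride frequency; turns occur every
hallway_length/walk_speed seconds as 180° rotation ramps over 2 s with
step pulses damped to 50%; white Gaussian noise is added per channel.
Defaults: 360 s, 50 Hz, cadence 100 steps/min, asymmetry 1.1, AP/vertical
pulse amplitudes 1.5/1.2 m/s², ML sway 0.8 m/s², noise SD 0.15 m/s²,
20 m hallway at 1 m/s — values in the range gait studies report for
community-ambulating lower-limb amputees.

Cohorts draw per-member cadence, asymmetry and noise SD from
class-conditional normal distributions: fall risk cadence 85 ± 8
steps/min, asymmetry 1.22 ± 0.08, noise 0.20 ± 0.03; no fall risk
105 ± 8, 1.06 ± 0.04, 0.15 ± 0.03 (clipped to physiological ranges).
Slower, more asymmetric, noisier gait in the fall-risk class encodes the
direction clinical gait research associates with instability; the ~2.5
pooled-SD cadence separation makes the cohort learnably, not trivially,
separable.

What passing synthetic tests shows: the pipeline's stages are correct and
leak-free, the detector can learn strike morphology from labelled data,
post-processing repairs realistic label corruption, and the feature →
CFS → forest chain recovers class structure planted in gait parameters.
What it does not show: performance on real amputee gait, whose waveform
variability (prosthetic-side morphology differences, aids, fatigue,
irregular turns) the generator deliberately does not model.

## Problem sizes

The test suite and acceptance script use scaled-down but structurally
complete experiments, the package's own choice of desk-scale defaults:
detector training on twenty 60 s walks with one held out; post-processing
repair on a 120 s walk (drop rate 0.1, duplicate rate 0.3); end-to-end
classification of an 80-member (27 fall-risk / 53 not) cohort of 90 s
walks, scored against the 53/80 majority rate by a one-sided binomial
test at α = 0.01.

## Known limitations

* The simulator's pulse-train waveform is analytically convenient, not
  biomechanically validated; absolute feature values are not comparable
  to clinical recordings.
* Side assignment from a single pelvis sensor is heuristic (ML-sway
  anchored alternation) and unvalidated against real left/right labels.
* REOH, quartile-FFT and peak-distinction definitions are package
  conventions; other implementations of the same feature names may
  differ numerically.
* The locking-period estimator assumes the opening 5 s contain steady
  walking; a trial that starts with standing still falls back to the
  minimum locking period.
* LOOCV with fold-internal CFS is O(n) selector runs; at a few hundred
  features and n ≈ 80 this is seconds, but it scales quadratically in
  feature count.
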