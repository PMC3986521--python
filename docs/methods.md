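# Methods

This note documents the models, parameters and numerical choices behind
`effortdecode`, and what the synthetic sessions do and do not establish.

## The decoding problem

A mover performs trial blocks consisting of a neutral segment followed by
think/do segment pairs for each of the eight Laban effort elements. Two
labeling schemes are decoded from EEG: `action` (neutral / think / do,
3 classes) and `effort` (neutral + {think, do} × 8 elements, 17 classes;
all neutral segments collapse into one class). The decoding features are
amplitudes of slow cortical activity: the delta band (0.2–4 Hz) carries the
class information, and short windows of its recent history (time lags) form
the feature vector.

## Preprocessing

Fixed order: reject → resample → band-pass → standardize → embed → label.

* **Peripheral rejection.** The default rejection list is the 25 outer-ring
  labels of the 64-channel extended 10–20 montage (frontopolar, anterior
  frontal, temporal, posterior temporal, parieto-occipital and occipital
  rows), which are the channels most contaminated by motion and scalp EMG;
  of 64 channels, 39 survive. Matching is case-insensitive; unknown labels
  warn rather than fail.
* **Transition trimming.** 500 ms (default) is removed at *both* ends of
  every segment. Trimming is applied to the schedule rather than by deleting
  samples, so the filters always see the continuous recording; segments
  shorter than twice the trim are dropped with a warning.
* **Resampling** to 100 Hz by polyphase FIR (anti-aliased; `padtype="mean"`
  keeps DC levels at the edges). Only downsampling is allowed.
* **Band-pass** 0.2–4 Hz, 3rd-order Butterworth applied forward-backward
  (zero phase). The pad length is 3 periods of the low edge
  (`3·rate/low` samples) because startup transients of a 0.2 Hz edge decay
  over seconds — scipy's default pad of a few dozen samples is far too
  short and leaks edge transients into the signal.
* **Standardization** per channel over the whole trial, population (1/n)
  SD convention. Zero-variance channels are an error naming the channel.
* **Lag embedding** with `l = 10` lags at 100 Hz (a 100 ms window): the row
  for time `t_n` concatenates samples `t_n−9 … t_n` channel by channel,
  giving `N·l` columns and `samples − l + 1` rows; the first row sits at
  the l-th sample so no row reaches before the recording.
* **Labeling** assigns each row the class of the segment containing its
  `t_n` (half-open `[start, end)` intervals); unlabeled rows are dropped.

## LFDA

Within-class affinities use local scaling:
`A_ij = exp(−‖x_i−x_j‖²/(σ_i σ_j))` with `σ_i` the distance from `x_i` to
its `k_nn`-th nearest *same-class* neighbor (duplicate points get a tiny
floor). Pair weights are `A_ij/n_c` (within-class scatter) and
`A_ij(1/n − 1/n_c)` same-class / `1/n` different-class (between-class
scatter); the scatter matrices are assembled per class through
`X'(D−W)X` identities, so no dense n×n weight matrix is formed and classes
larger than 5000 rows are subsampled (seeded) for the O(n²) affinity step.
The transform is the top-`r` generalized eigenvectors of `S_b v = λ S_w v`
(scipy's symmetric solver), each scaled to unit norm with a deterministic
sign (largest-magnitude entry positive). If the solve fails on a singular
`S_w` — lag-embedded features are highly collinear — a ridge of
`1e-9·trace(S_w)/d` is added with a warning. With uniform affinities the
construction reduces exactly to classical Fisher discriminant analysis,
which is the correctness oracle in the tests. Column signs are a genuine
indeterminacy; classification is invariant to them (tested).

## Per-class Gaussian mixtures

Each class density is `p(x) = Σ_k α_k φ_k(x)` with full covariances
(lag-embedded EEG features are correlated, so diagonal families are not
offered). For every `K ∈ {1..K_max}` (default `K_max = 10`) parameters are
initialized from a seeded k-means partition and refined by EM until the
log-likelihood improves by less than 1e-6 (relative) or 500 iterations.
The log-likelihood is asserted non-decreasing at every iteration; E-steps
are computed in log space via Cholesky factors, with a `1e-6·mean(diag)`
jitter retry when a covariance loses positive definiteness and a constant
1e-12 diagonal floor in the M-step. `K` is selected by minimum BIC with the
full free-parameter count `p = (K−1) + K·r + K·r(r+1)/2`:
`BIC = −2L + p·log n`. A fixed-penalty variant `−2L + 2·log n` is
selectable (`mode="as-printed"`) for comparability with formulations that
write the penalty without the parameter count; it never penalizes larger K
and is not the default. One k-means restart per K is the default
(`n_restarts` configurable): with seeded initialization the fit is already
deterministic, and restarts showed no accuracy benefit on these sessions
while tripling the dominant cost of cross validation. A greedy
component-insertion variant (`init="greedy"`: new component seeded at the
worst-explained training point) is available behind a flag.

Classification uses equal class priors — the cross-validation design keeps
classes balanced, so the posterior is the normalized per-class mixture
density — and ties break to the lexicographically smallest label.

## Cross validation and channel selection

Per iteration (default 10), `floor(pct_train% · least-populated-class)`
rows per class are drawn for training and an *equally balanced* disjoint
test set of `min_c(n_c − n_train)` rows per class is scored; balanced test
sets make accuracies directly comparable to `1/#classes` chance. The full
LFDA+GMM stack is refit on training rows only. Reported: per-iteration
accuracies, mean, SD, standard error (SD/√n_iter) and the pooled confusion
matrix. Forward selection scores each candidate channel (all `l` of its lag
columns) with a 3-iteration inner CV, greedily grows the selected-channels
list, and re-estimates the final accuracy curve with 30 iterations; `r` is
capped at the candidate set's column count so one-channel sets are
solvable.

**Known optimism.** Rows are sampled without regard to temporal adjacency,
mirroring the random sub-sampling design. Band-limited (0.2–4 Hz) features
change slowly relative to the 10 ms row spacing, so train and test rows
interleave on the same per-segment signal trajectories. Two consequences,
both demonstrated in the test suite: (i) the shuffled-label guard is at
exact chance — there is no label leakage; (ii) a *null-signal* session
(class SNR 0) still scores far above chance on the effort scheme, because
per-segment noise trajectories identify the segment and segments coincide
with classes. The effect survives replacing the 1/f background with white
noise — it is inherent to the combination of in-band autocorrelation and
temporally interleaved sampling, not to the generator. Accuracies from this
CV design therefore bound within-session decodability, not generalization
to new recordings; a session-split design would be the stricter test and is
deliberately out of scope here because the evaluated method is defined by
its random sub-sampling scheme.

## Synthetic sessions

The generator emulates one continuous recording: per block, a neutral
segment then think/do pairs for the eight elements (condensing element
always before the indulging one within a factor), default 10 s per segment
and 3 blocks (~8.5 min). Defaults emulate the acquisition setup (64
channels at 1000 Hz, 10 sensors at 128 Hz); tests and the acceptance script
use 16 channels at 100 Hz so the full pipeline runs in minutes on one CPU.

* **EEG** = unit-variance 1/f-shaped background per channel, plus per-class
  narrow-band Gaussian processes (band-pass filtered white noise, centre
  frequency drawn per class from 0.6–3.8 Hz, ±0.4 Hz width) mixed through
  class-specific random spatial patterns, scaled to microvolts. Patterns
  have unit RMS *per channel*, so `class_snr` (default 1.0) is the
  per-channel amplitude of the class component relative to the background;
  at this default the 17-class pipeline decodes in the ~94 % regime,
  matching the high-80s operating point of real sessions of this kind.
* **Accelerometry** = smooth (≤8 Hz) noise per axis, modulated by a
  per-condition intensity and a log-normal envelope
  (`exp(σ·g − σ²/2)`, `g` a slow GP): do/light and do/sustained are small
  and steady (low envelope spread), do/free and do/quick large and bursty
  (high spread), so PC1 score distributions mix sub- and super-Gaussian
  shapes across classes. Head/trunk sensors move less than limb sensors.
* **Artifact coupling**: per-class κ ∈ [0,1] adds κ × standardized
  head-acceleration magnitude (interpolated to the EEG rate) through a
  fixed random spatial pattern. κ = 0 by default — coupling is an injected
  contamination to be recovered by the QC, not a property of clean
  sessions.

What the generator does *not* emulate: volume-conduction geometry and
realistic scalp topographies, eye/muscle artifacts, non-stationary
background spectra, inter-subject variability, and any relation between the
imagined (think) and enacted (do) signatures of the same element — each
class is statistically independent. Passing tests therefore show the
pipeline recovers structure *of the assumed form*; they say nothing about
whether real EEG contains such structure.

## Artifact QC

PCA is computed over the per-sensor acceleration-magnitude series (mean
centered, SVD); kurtosis of PC1 is reported per class in the plain
convention (Gaussian = 3). Correlation maps use zero-lag Pearson ρ per
channel over the concatenated samples of one class, between a movement
reference (head-acceleration magnitude or PC1 "synergy", linearly
interpolated to the EEG grid) and the *resampled but unfiltered* EEG —
the audit asks how much broadband EEG the movement explains. Class-level
summaries use the median of |ρ| across channels: the injected artifact
pattern has random per-channel signs, so a signed median would cancel.
Spectrograms use 1024-sample Hann windows with 93 % overlap, 0.1–40 Hz;
coherence uses Welch averaging with 1024-sample Hann segments at 50 %
overlap (at least two segments required). The audit statistic pairs each
class's F1 with its median |ρ| and reports the Spearman rank correlation
with a one-sided (positive) permutation p-value (10 000 shuffles); a
constant input yields ρ_s = 0, p = 1 by convention.

## Laban-space projection

Every non-neutral class maps to (factor, sign): indulging elements to +1,
condensing to −1 on their factor axis. A posterior row projects to
`coord_f = Σ_{classes on f} sign · P(class)`; think and do posteriors of
the same element pool, neutral contributes nothing, so coordinates are
linear in the posterior and bounded in [−1, 1]. Rows with
`max_f |coord_f| < τ` (default τ = 0.1) are flagged non-expressive —
confident predictions sit at octahedron vertices, uncertain or
neutral-dominated ones near the origin.

## Problem sizes used in tests and the acceptance script

Headline runs use 16 channels at 100 Hz, 3 blocks × 17 × 10 s segments
(≈46k feature rows, 160 features, 17 × 2700 labeled rows), LFDA `r = 70`,
`k_nn = 7`, `K_max = 10`, 10 CV iterations at 50 % training — a few
minutes on one CPU. Null-signal controls use 2 blocks of 6 s segments.
Unit tests run on toy problems (hundreds of rows) against closed-form
oracles.
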