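# Methods

## Overview

`attneeg` models the link between a latent sustained-attention state and two
of its observable signatures — reaction time in an AX-CPT task and the
temporal irregularity of frontal EEG — and provides the full recognition
pipeline on top: preprocessing, calibrated-RT labeling, single- and
multiscale complexity features, spectral baseline features, cross-validated
classification, and dynamics–behavior correlation. Because no recorded
dataset ships with the package, a synthetic-cohort generator defines the
test conditions; it is first-class, tested code.

## The synthetic cohort

Each simulated session is a 3-minute (default) resting block followed by
192 trials (144 "AX", 48 other), each trial occupying a 3-s epoch window
plus an inter-trial interval drawn uniformly from {1.5, 2.0, 2.5} s.

**Latent attention.** A stationary AR(1) process z_t (coefficient 0.9,
unit variance) mapped through the normal CDF gives a per-trial latent state
u_t ∈ [0, 1] that drifts slowly over the session — slow enough to produce a
meaningful time-varying trajectory for the dynamics analysis, fast enough
that each subject visits high and low states.

**Behavior.** log RT_t = log 420 ms + b_s − 0.6·u_t + 0.2·ε_t, with a
per-subject speed offset b_s ~ N(0, 0.15²) (log-ms). The slope/noise ratio
yields a latent-to-RT Spearman correlation around −0.5, so α-quantile labels
recover the latent level well above chance while staying realistically
noisy; the marginal of log RT remains close enough to normal that a
D'Agostino–Pearson test rarely rejects at n = 192 (the generator's RT
histogram is approximately log-normal, as in real CPT data). A flat 2 %
error rate marks incorrect responses; error trials are retained for
labeling.

**EEG.** Each channel is a unit-variance mixture
√(1−p)·pink + √p·white, scaled to 20 µV RMS, where the white-noise
variance fraction is

    p(t) = 0.05 + 0.10 · g_s · entropy_effect · d(t) · channel_scale,

with drive d(t) = 0 at rest and 0.5 + u_t during a trial slot,
channel_scale = 1 for the 13 frontal electrodes and 0.5 elsewhere (or 0
with `frontal_only_effect`), and a subject-specific gain g_s ~
exp(N(0, 0.3²)): subjects express the effect with different strength, so a
classifier trained on other subjects generalizes imperfectly even after
per-subject normalization (which removes additive offsets but not the
separation-to-noise ratio) — this is what makes epoch-pooled 5-fold CV run
above leave-one-subject-out CV, as it does on recorded cohorts. The task
floor of 0.5 keeps even low-attention task epochs more irregular than
rest. The entropy of the mixture is concave in p with a ceiling at the
white-noise value, so the gain of 0.10 is sized to keep even
entropy_effect = 2 with a high-gain subject in the quasi-linear region
(p ≲ 0.5); this makes `entropy_effect` behave as a monotone effect-size
dial, which the recovery tests rely on. An 8–13 Hz oscillation (amplitude
1.2 at rest, 0.3 during task, in background-SD units) makes resting EEG
both more regular and more alpha-dominant. Optional artifacts: a 50 Hz
sinusoid (line noise) and
raised-cosine 300-ms blink transients (200 µV) propagating from the eyes
with gains decaying toward posterior sites; EOG leads carry half the
cerebral background, so the blink component correlates strongly with EOG.

**What the generator does not emulate:** volume conduction and channel
covariance (channels are independent noise), non-stationary drift,
muscle/movement artifacts, realistic AX-CPT error psychology, or
band-specific attention effects beyond the alpha/rest contrast. Passing
tests therefore demonstrate that the pipeline recovers the planted
structure under controlled conditions, not that the accuracies transfer to
recorded EEG.

**Determinism.** Subject i's seed derives from (master_seed, i) only, so a
subject's data are invariant to cohort size; two runs with the same config
are bit-identical.

## Preprocessing

The notch is an IIR zero-phase filter at 50 Hz (2 Hz bandwidth); the
band-pass is a 3rd-order Butterworth, 0.3–70 Hz, applied forward-backward
(`sosfiltfilt`) so epochs stay time-locked to stimulus onsets. Ocular
cleaning decomposes the 32 EEG channels into 30 independent components
(FastICA, fixed seed), zeroes every component whose absolute correlation
with either EOG lead reaches 0.7 (configurable), and back-projects the
rest; if nothing crosses the threshold the recording is returned unchanged.
FastICA's stopping tolerance is rarely met when most background sources are
near-Gaussian, so after three seeds the implementation proceeds with the
last fit under an error-level log instead of refusing to clean the
recording — the correlation-based rejection does not require a fully
converged unmixing.

Epochs are half-open [onset, onset + 3 s) windows, one per trial; the rest
block is tiled into non-overlapping 3-s RS epochs (floor division, 3 min →
60 epochs). Epoching never resamples or rescales: concatenating task epochs
reproduces the raw samples exactly.

## Labeling

C-RT = RT − mean(RT) within subject (subtraction, not ratio): labels then
depend only on within-subject rank, so they are invariant to any constant
per-subject speed offset. A single-pass |C-RT| > 3 SD rule removes outliers
(~1–2 trials per 192). With quantile α, the fastest round(α·n) surviving
trials are HA and the slowest round(α·n) are LA; ties break by trial order
(earlier trial takes the more extreme label, and LA skips trials already
claimed by HA in the fully-tied degenerate case). α grows symmetric nested
sets, so no trial ever flips between HA and LA as α changes.

## Complexity features

ApEn (m=2, r=0.2·SD) includes self-matches over N−m+1 templates; SampEn
(m=2, r=0.15·SD) excludes them over N−m templates; both use the Chebyshev
distance with closed-ball matching (equality has probability zero for
continuous data). FuzzyEn (m=2, r=0.15, n=2) removes each template's mean
and uses the membership exp(−d^n/r). Because that exponent is not
amplitude-homogeneous for n ≠ 1, the series is standardized to unit SD
first: distances are then in SD units and all three estimators are exactly
invariant to amplitude scaling. Constant series return 0 (the
all-templates-identical limit). An undefined SampEn (no length-(m+1)
matches) is reported as missing, never imputed, and poisons the area index
loudly rather than silently.

Multiscale curves coarse-grain by non-overlapping block means (trailing
partial block dropped) for τ = 1…50 and hold the tolerance fixed from the
scale-1 series (for MFE, by standardizing once at scale 1). MSEI/MFEI are
trapezoidal areas over scales 1–10 — beyond scale ~10 the class curves
overlap, and at 3-s epochs the coarse series get short (low-N estimates are
logged). The implementations are vectorized via condensed pairwise-distance
arrays; tests pin them to literal double-loop references at 1e−12.

ApEn's self-match bias matters at these sizes: for i.i.d. Gaussian data at
N = 3000, m = 2→3, the expected match count at m+1 is only ≈ 4, so the +1
self-match depresses ApEn by ≈ 0.15–0.2 below the asymptotic limit
−ln erf(r/2); SampEn, which drops self-matches, sits on its limit. The test
suite asserts both against the analytic limit and documents the ApEn bias.

## Spectral baseline

A 7-level wavelet packet transform tiles [0, fs/2] into 128 uniform bands;
terminal nodes are taken in frequency (sequency) order and assigned to
θ (4–8), α (8–13) or β (13–30 Hz) when ≥ 50 % of a node's interval overlaps
the band (at 1 kHz sampling the 3.9 Hz nodes cannot match 13 Hz edges
exactly, so a deterministic rule is required). Band power is the Welch PSD
(1-s Hamming windows, 50 % overlap) of the reconstructed band signal
integrated over the band; β/θ, β/α and β/(α+θ) are the features. The
default wavelet is sym16: short filters (db4) leak > 15 % of an in-band
sinusoid's variance into neighboring level-7 nodes through aliasing
sidelobes, while sym16 keeps ≥ 90 % in-band with < 5 % leakage (the
sinusoid-sweep test enforces this). A config switch computes the Welch
ratios on the raw epoch instead of the reconstructions.

## Classification

Feature matrices are min-max normalized to [0, 1] per subject and per
column (idempotent; a within-subject constant column maps to 0.5 with a
warning). Two validation schemes are reported deliberately side by side:
leave-one-subject-out (honest cross-subject generalization) and epoch-level
stratified 5-fold pooled across subjects, in which epochs from the same
subject — and temporally adjacent, highly correlated trials — appear in
both training and test folds. The 5-fold numbers are therefore expected to
run well above LOOCV; the suite asserts this gap on cohorts with
subject-specific offsets and the documentation treats 5-fold as an
optimistic upper bound, not a generalization estimate.

Models: XGBoost (hist, 200 rounds), RBF SVM, and 500-tree random forest,
each single-threaded for reproducibility. Optional hyperparameter tuning is
an inner stratified 3-fold grid search on the training fold only (XGBoost
depth {3,6} × learning rate {0.1,0.3}; SVM C {1,10}); the scaled-down
acceptance runs disable tuning for runtime. Multi-class ROC uses pooled
out-of-fold scores with macro one-vs-rest averaging. Importance is XGBoost
total gain (gain × use count) averaged across folds, ties broken
lexicographically — per-split mean gain lets a single lucky split on a
noise column outrank consistently used informative features when columns
outnumber rows. Class imbalance in the 2-level task is left unweighted
(accuracy is the reported metric; balanced accuracy is available on the
report object). Chance-level and effect-size recovery tests balance the
classes by subsampling first: with the protocol's natural imbalance (MA is
twice HA/LA) a permuted-label model still learns class priors and beats
1/k, and at weak effects a flexible model can dip below the majority-class
rule, making raw accuracy non-monotone in effect size.

## Statistics and dynamics

Group comparisons gate on normality: if every group passes the
D'Agostino–Pearson test (p > 0.05; groups under 8 observations count as
non-normal since the kurtosis component needs n ≥ 8), one-way ANOVA is
used, otherwise Kruskal–Wallis. Channel maps bin p-values into
(0.01, 0.05], (0.001, 0.01] and ≤ 0.001; no multiple-testing correction is
applied by default (raw per-channel bins are reported), matching common
practice for topographic significance displays.

For dynamics, each subject's surviving task trials give a trials × 13
matrix of one frontal feature; PC1 scores (SVD on the column-centered
matrix) summarize it, with the sign fixed so PC1 correlates positively with
the channel-mean trajectory — eliminating backend-dependent sign flips.
Subjects are truncated to the shortest surviving-trial count and averaged
position-wise (no smoothing, no interpolation); Spearman correlation of the
averaged PC1 against the averaged C-RT trajectory is the headline statistic.
With the generator's negative coupling (more attention → more irregular EEG
and faster RT), the recovered correlation is negative.

## Orchestration and problem sizes

`run_pipeline` executes simulate → preprocess → label → features →
classify → stats from one YAML config; a single master seed fans out to
per-stage seeds via `SeedSequence([master, stage_tag])`. Every stage
persists its outputs, and the manifest records SHA-256 checksums, so a
rerun (or a resume from cached features, gated on a config fingerprint that
excludes the output path) is bit-identical.

Pairwise-distance entropy is O(N²) per channel-epoch, so the test and
acceptance cohorts are scaled down, as the package's own choice of problem
size: 8 subjects × (64 trials + 1-min rest) at 400 Hz with multiscale
scales 1–10 for the main recovery cohort, 3-subject cohorts for the
effect-size sweep and the importance scenario; structural checks (192
trials, 60 rest epochs, 50-scale curves, 65/39 feature dimensions) always
run at the full design sizes. 400 Hz keeps the τ = 10 coarse series at 120
samples, above the length where SampEn starts going undefined at r = 0.15.

## Known limitations

* The synthetic EEG has no cross-channel covariance, so ICA separates
  sources more cleanly than it would on recorded data.
* 5-fold accuracies are optimistic by construction (see above); LOOCV is
  the number to quote for cross-subject claims.
* MSEI requires all scales 1–10 defined; very short or very regular epochs
  can lose the feature (the epoch is then dropped from the matrix, logged).
* EDF export is not implemented (recordings persist as matrix + JSON
  header); EDF reading is available through mne.
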