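# Methods

This note documents the models, numerical choices and limitations behind
`bradykin`.  Empirical statements below are the quantities the test suite
and `scripts/acceptance.py` themselves compute.

## Synthetic movement model

The generator emulates the structure of a bradykinesia assessment cohort —
subjects performing 5 tasks × 2 sides, rated 0–4 (4 folded into 3) — not the
biomechanics of real limbs.  Each movement event is a raised-cosine pulse of
60 ms width: smooth, band-limited, wavelet-friendly, with a single-sample
maximum whose value equals the event amplitude exactly, so amplitude
decrement is recoverable in closed form (`A·(1−d)^k` for cycle `k`).

Linear tasks (FT/HM/TT/LA) place a closing peak every `1/base_rate` seconds
and an opening peak half a period later at a uniform 0.4–0.6× ratio (the
ratio is an exposed parameter; at ≤ 0.3 the opening peaks fall below the
low-amplitude filtering threshold and the ground-truth closing peaks become
the exact detection target).  The rotational task (PS) alternates plateaus of
±A/2 at two transitions per cycle, with a spike at each transition onset
whose sample value equals the cycle amplitude.  Hesitations insert pauses
after a cycle with the profile's probability; tremor is a 5 Hz sinusoid with
a random phase per axis; sensor noise is i.i.d. Gaussian; gravity is a
constant 9.81 m/s² on the z-axis.

Default severity profiles (documented constants, not measurements):

| score | rate (mov/s) | amplitude (m/s²) | decrement/cycle | hesitation prob | pause (s) | tremor (m/s²) |
|------:|-----:|-----:|------:|------:|-----:|------:|
| 0 | 2.5 | 1.5 | 0.00 | 0.00 | 0.5 | 0.00 |
| 1 | 2.0 | 1.2 | 0.03 | 0.05 | 0.5 | 0.02 |
| 2 | 1.5 | 0.9 | 0.08 | 0.15 | 0.6 | 0.05 |
| 3 | 1.0 | 0.6 | 0.15 | 0.30 | 1.0 | 0.08 |

`noise_sd` defaults to 0.02 m/s².  Pause length grows with severity; with a
fixed pause the interval coefficient of variation would not order strictly
with the score (the pause-to-period ratio of a slow rhythm shrinks), and a
strictly ordinal difficulty structure is a design requirement of the
generator.  Clinically this matches hesitation episodes lengthening with
severity.  Cohorts draw one severity score per subject (subject-level
severity), jitter the profile multiplicatively per subject (5%/8% SD on
rate/amplitude) and per recording (3%/4%), and sample ages from N(66, 10²)
clipped to 40–90.  The default score composition (6, 14, 3, 6)/29 for scores
0–3 reflects a pooled 29-participant test-session distribution of the
finger-tapping item; `exact_counts=True` allocates it deterministically by
largest remainder.

What the simulator does **not** model: realistic limb dynamics and gravity
reorientation, gyroscope channels, rater disagreement, non-stationary tremor,
or correlated sensor noise.  Passing tests therefore demonstrate that the
pipeline recovers the severity structure it encodes — slowness, hesitation,
decrement — not clinical performance on patients.

## Denoising

Per axis: db4 wavelet decomposition at level 4 with symmetric extension,
hard thresholding of all detail levels at the universal threshold
`σ√(2 ln N)`, with `σ = MAD/0.6745` estimated from the finest detail level
only.  Two deliberate choices: (1) the finest-level σ — coarser levels carry
the 2–5 Hz movement band, and a per-level estimate inflates the threshold
enough to erase the movement peaks; (2) hard rather than soft thresholding —
soft shrinkage biases the amplitude of sharp transients downward, and peak
amplitudes are the raw material of the decrement features.  With
thresholding disabled the transform round-trips the input to 1e−9
(orthogonal filter bank), which the tests use as the identity check.

## Peak detection

The AMPD variant is fully deterministic: the local-maxima scalogram holds
0/1 entries (`x[i] > x[i±k]`), not random fill.  The scale λ is the row with
the most *interior* maxima — near the half-period of a quasi-periodic signal
almost every sample of the dominant lobe beats both k-distant neighbours, so
λ tracks the rhythm.  Candidates must be maxima at *every* scale 1..λ, with
an out-of-range neighbour comparison counting as satisfied so that a
dominant first/last-in-window sample can surface (the boundary rule then
removes candidates at the exact first/last sample; interior first peaks are
kept).  Constant and linear signals yield no candidates (a relative
tolerance absorbs detrending float dust).  λ is capped at ⌈N/2⌉−1.

The amplitude rule keeps candidates at ≥ 0.3× the highest candidate
amplitude (ties retained).  The flat rule computes
`s[i] = Σ |x[n+1]−x[n]|` over `n ∈ [i−2, i+1]` (clipped) and keeps
candidates with `s > 0.1 × max s` — the reference "highest amplitude" is the
windowed-derivative signal itself, the unit-consistent reading; the sharpest
candidate is always retained.  Both thresholds are relative, so the retained
set is invariant to positive rescaling.  Peaks are detected per segment, not
per recording, because all downstream features are per-segment.

Measured fidelity (also recomputed by the acceptance script): pooled
matched-peak F-score ≈ 0.998 (±3-sample tolerance) over 50 seeds × scores
0–3 at `noise_sd = 0.05 × amplitude` with opening peaks at 0.25×.  At the
default 0.4–0.6× opening ratio the opening peaks legitimately survive the
0.3 rule, so detections exceed the closing-peak ground truth by design.

## Features

126 sub-features per segment.  Definitions the source material leaves open
are pinned here and versioned in the shipped schema manifest
(`feature_schema.json`):

* **FatigueN** (N ∈ {1, 2, 5}) = (mean of last N − mean of first N)/(mean of
  first N) of a peak series; windows may overlap when the series is shorter
  than 2N; sentinel 0 below N values.  Quantifies the sequence effect.
* **AscdF/DscdF** = fraction of consecutive strictly increasing/decreasing
  steps; rhythm-instability counterparts.
* **Entropy** = Shannon entropy (bits) of a 16-bin histogram over the
  observed range (scale-invariant by construction).
* **IQR** = interquartile range of the biased autocovariance at lags
  0..N/2; **H** = harmonic mean of |x|+1e−8; **ARC** = Burg AR(4)
  coefficients; **CrossCorr** = peak normalized cross-correlation against
  the magnitude channel (exactly 1 for the magnitude channel itself).
* **DFA** = log–log slope of the detrended fluctuation function over box
  sizes 4, 8, …, N/4 (≈ 0.5 for white noise).
* Spectral features use the one-sided boxcar periodogram with the DC bin
  excluded: MainF/MainAmp (argmax bin), MeanF (spectral centroid), SE
  (entropy normalized by log of the bin count).  **Spectral flatness** is
  the geometric/arithmetic mean ratio of an 8-block Bartlett-averaged
  periodogram: a raw periodogram's bins stay χ²-distributed at any length,
  which pins white-noise flatness near `exp(−γ) ≈ 0.56`; block averaging
  makes the estimator consistent so flatness → 1 for white noise while a
  tone still collapses to one bin.  ε-floors: 1e−20.
* Degenerate inputs (< 2 peaks, < 32 samples, zero spectra) produce sentinel
  0.0, never NaN; the assembled matrix is always finite.

Gender is encoded 0/1 (M/F), age in years, unscaled — standardization
happens inside model pipelines only.

## Selection and evaluation protocol

The protocol is nested by default: inside every LOSO fold, feature ranking
(single-feature weighted F1 of an untuned RBF SVM under subject-grouped
3-fold CV), greedy forward selection (strict-improvement rule over the top
20 ranked features), and hyperparameter tuning see only training subjects; a
`global_selection` flag instead selects features once on the full dataset,
a flatter and faster (but optimistically biased) protocol.  A reference
selection on the full cohort is always reported as the deployable feature
set.

Tuning searches the fixed grids: exhaustive when the space has ≤ 2
dimensions (SVM, KNN, NB), otherwise a seeded random draw of 10
configurations (DT, RF, GBDT, LR) — the budget keeps nested tuning inside
29 folds × 7 models × 3 scenarios tractable; the small
`n_estimators` grids (≤ 30) make individual fits cheap.  Inner scoring uses
grouped 3-fold CV with SMOTE applied to inner training folds only.  SMOTE
(implemented in-package) oversamples every class to the majority count —
exactly 1/k of the training set per class — by convex combinations of
same-class nearest neighbours (k = 5, reduced for tiny classes; a singleton
class is duplicated, with a log warning).  SVM probabilities come from
sklearn's Platt-style internal calibration; hard voting exposes vote
fractions as pseudo-probabilities; stacking uses a logistic-regression
meta-learner on out-of-fold member probabilities (3-fold); AdaBoost wraps
the optimal model with 50 boosting rounds, falling back to the bare base
model on folds where the base errs worse than chance (boosting undefined),
and adapts bases without `sample_weight` support (KNN) via weighted
bootstrap resampling.

Record-level predictions are the majority vote over a record's segments,
ties broken toward the severer class (clinically conservative screening
choice); record probabilities are segment means.  RMSE treats scenario
classes as ordinal indices; AUC is class-weighted one-vs-rest.  Bootstrap
CIs resample records within true-class strata, 2,000 replicates, percentile
2.5/97.5; undefined replicates (e.g. single-class AUC) are redrawn and
counted.  McNemar uses the exact two-sided binomial p below 25 discordant
pairs, else χ² with continuity correction, at a Bonferroni-adjusted
α = 0.05/(number of alternatives).  An instrumentation hook records the
subject ids each phase touches and asserts the held-out subject never
appears in a training-side phase.

## Study sizes and measured recovery

The synthetic study uses 29 subjects, 12 s recordings (five 4-s windows at
50% overlap, ~145 segments per task-side), the default profiles and the
default score composition — sizes chosen so the full three-scenario study is
a desk-scale computation.  At these conditions the pipeline reaches
record-level weighted F1 ≈ 0.96 (precise), ≈ 0.96 (abnormal) and 1.00
(critical), with critical ≥ precise; the binary scenarios sit at or above
the 4-class one except where a single borderline subject (a fast score-1
mover or slow score-0 mover) flips one record — with ~29 records one record
is ≈ 0.035 of weighted F1.  These numbers quantify parameter recovery on
synthetic data only.

## Shapley attributions

`shap_importance` computes interventional Shapley values exactly by subset
enumeration for up to 10 features — `v(S) = E_bg[f(x_S, z_{\bar S})]` over a
background sample (≤ 100 rows), combined with the standard Shapley weights —
and falls back to seeded permutation sampling beyond that.  Local accuracy
(attributions sum to prediction − base value) holds to float precision in
exact mode and is asserted in tests; a feature constant across the
background and the explained point receives exactly zero attribution.

## Known limitations

* Synthetic-only validation; the clinical feature set's behaviour on real
  accelerometry is untested here.
* The rotational-task transition spikes ride on alternating plateaus, so at
  high decrement the relative-amplitude filter can drop late transitions —
  informative for severity scoring but a deviation from the ideal detector.
* Greedy forward selection examines only the top 20 ranked features and
  stops at the first non-improving candidate per rank position; it is a
  heuristic, not an optimal subset search.
* The stacking meta-learner's internal 3-fold split is stratified but not
  subject-grouped (it operates inside an already subject-clean training
  fold).
* Bootstrap CIs treat records as exchangeable within class strata; with one
  record per subject per task this matches subject-level resampling.
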