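# Methods

## Signal model and preprocessing

A `Recording` is a time × channels matrix at a declared sampling rate
with subject and condition metadata. The preprocessing chain mirrors a
standard ECoG workflow: a 4th-order Butterworth band-pass (default
0.5–100 Hz) applied forward–backward at the acquisition rate, one
second trimmed from each end to discard filter edge transients, then
polyphase rational downsampling to the analysis rate (1000 → 256 Hz is
the ratio 32/125, with the resampler's built-in anti-alias low-pass).
Zero-phase filtering is deliberate: the fractal-dimension estimator is
sensitive to waveform shape, and causal filtering would distort it
through group delay. Epochs are whole-session, one per channel.

Two consequences of this chain are worth knowing. First, band-pass
filtering is only idempotent on passband content: signals with a steep
1/f²-like spectrum keep losing transition-band energy on repeated
passes (≈15 % RMS on fractional Brownian motion), because a 4th-order
edge at 0.5 Hz is soft where such spectra carry most of their power.
Second, the 100 Hz low-pass followed by 256 Hz resampling smooths the
two or three finest HFD scales, which compresses dimension estimates at
very small `k_max` toward 1 for every group alike.

## Higuchi fractal dimension

`curve_length_lm` is a direct transcription of the normalized
curve-length definition with 1-based indexing; the summation runs to
`⌊(N−m)/k⌋`, the only upper limit consistent with the normalization
factor. A vectorized path (`aggregate_length`) computes all offsets of
a scale in O(N) by binning lag-k increments by their offset class; it
is tested for exact agreement with the naive double loop. The offset
average requires every offset to contribute at least one increment
(N ≥ 2k); infeasible scales raise a typed error naming the largest
feasible `k` rather than silently averaging a partial set of offsets.

The dimension is the OLS slope of `log L(k)` on `log(1/k)` over
`k = 1..k_max` (natural logs; the slope is base-invariant). Estimates
are not clamped to [1, 2]: the bound is a property of the idealized
dimension, and clamping would hide estimator bugs. Constant (dead)
channels make every `L(k)` zero and raise `DegenerateSignalError` so
cohort pipelines fail loudly. Analytic anchors used in the tests: a
linear ramp gives exactly `L(k) = (N−1)/k`, hence fd = 1 with R² = 1;
white Gaussian noise gives fd ≈ 2; fractional Brownian motion with
Hurst exponent H gives fd ≈ 2 − H (verified to ±0.1 at N = 4096 over
50 paths for H ∈ {0.2, 0.5, 0.8}).

## Scaling-region selection of k_max

`L(k)` is only a power law where the series is self-similar;
preprocessing and noise floors bend the log–log curve at small scales.
`detect_onset` returns the smallest `k_onset` such that the suffix
`k_onset..k_eval` (default `k_eval` = 100) fits a line with
R² ≥ 0.99, scanning candidates in increasing order so the first
crossing — the widest usable region — wins. Two numerical guards:

* a minimum segment length (default 10 scales), because any 2-point
  suffix has R² = 1 by construction and short segments are not
  evidence of self-similarity;
* detection failure raises an error carrying the best (k, R²) found,
  rather than returning a meaningless onset.

The suffix-R² rule is deliberately insensitive: a mild slope kink deep
inside an otherwise straight curve barely moves R², so onsets respond
only to pronounced pre-onset bends. On constructed piecewise curves
with a sharp bend the onset is recovered within ±1 scale; on curves
that are already near power laws (including the synthetic cohorts
below) the detector correctly reports `k_onset = 2` — the whole curve
is the scaling region.

Group-level detection uses the point-wise geometric mean of the group's
epoch curves (averaging in log space matches the domain of the fit),
and `harmonize_kmax` takes the upper bound of the group-specific
onsets so every group's linear region lies inside the common fit range.

## Synthetic cohorts

The generator emulates the data regime the pipeline targets: 8
parkinsonian (PD) and 7 control subjects, 8 channels, 300 s sessions at
1000 Hz analyzed at 256 Hz, with a chronic design (baseline and
DBS-like treatment session per subject) and an acute design (each
subject recorded drug-free, after induction, and after rescue; 6
subjects).

Complexity is controlled through the Hurst exponent of an fBm
background (control H = 0.65, PD H = 0.45, so PD carries the higher
dimension), sampled exactly by circulant embedding of the fractional
Gaussian noise covariance. Amplitude is irrelevant to HFD (affine
invariance), so groups differ only in H. Per-subject and per-channel
Hurst jitter (sd 0.02 each) provide between-subject variability and
make the 8-channel feature vector informative but not degenerate;
channels share a common background component (weight 0.4) plus an own
component, plus amplitude jitter (sd 0.05). The treatment session
regenerates the background at
`H = H_pd + 0.8 · (H_control − H_pd)`, i.e. treatment closes 80 % of
the complexity gap; DBS-like treatment of controls leaves them
unchanged. Per-subject/-condition seeds derive from the cohort seed via
`SeedSequence(entropy=seed, spawn_key=(group, index, condition))`, so
adding subjects never perturbs existing ones and cohorts are exactly
reproducible.

Beta-band (12–30 Hz) burst packets (Hann-windowed sinusoids, 0.5 s,
Poisson arrivals at 0.5/s for PD vs 0.1/s for controls) and a white
measurement-noise floor are included as phenomenology, but their
default amplitudes (0.002 and 0.0005 of the background SD) are
deliberately vestigial. The reason is a scale mismatch: at HFD scales
(4–120 ms) the unit-SD fBm background has local increments of order
10⁻³–10⁻², so an additive component that looks small relative to the
whole path dominates the fine-scale structure — and it inflates the
*smoother* group's curve lengths first, which can compress or even
invert the group ordering the cohort is meant to encode. With the
defaults, group separation is driven by H, as intended.

What passing tests on these cohorts do and do not show: they validate
the estimator, the selection rule, the statistics and the classifier on
signals whose ground truth is known; they do not demonstrate spectral
realism (real ECoG carries strong rhythms and a measurement-noise floor
that bend the log–log curve well beyond k = 2, which is why empirical
studies find onsets around 19–31 while scale-free synthetic cohorts
yield `k_onset = 2`), nor artifact robustness, nor volume-conduction
structure.

## Group statistics

`rm_anova_oneway` and `mixed_anova_twoway` are conventional
sums-of-squares decompositions: within-subject F with df
`(c−1, (c−1)(n−1))` for the acute design; for the mixed design the
between effect is tested against subjects-within-groups (df `n−g`,
giving the (1, 13) shape for 8 + 7 subjects) and the within effects
against the subject × treatment residual (df `(n−g)(t−1)`). Both are
cross-checked against pingouin and against hand-coded decompositions
in the tests, and their type-I error is calibrated to 0.05 ± 0.015
under 2000-rep null simulations. No sphericity correction is applied:
the chronic within factor has two levels (sphericity holds trivially),
and none is applied for the three-level acute design. Missing cells are
an error — no imputation.

Fisher's LSD is a plain t test on the ANOVA's error mean square
(between-error for group comparisons, within-error for treatment
comparisons, optionally restricted to one group for simple effects),
with *no* multiplicity adjustment — that is the definition of the
procedure and is intentional; with two conditions it reduces exactly to
the paired t test, and for two groups the squared LSD t equals the
group F. Shapiro–Wilk (per cell and on residuals) and Levene screening
warn at p ≤ 0.05 but do not abort, matching their role as an
acceptance check for the parametric analysis.

The ANOVA unit is the channel-averaged FD per subject and session
(channels are repeated measurements of one cortical state; averaging
is consistent with subject-level degrees of freedom). Per-channel
analysis remains available by passing the tidy table directly.

## Classification

Features are the per-channel HFD values of the baseline sessions, one
row per subject, PD as the positive class. The classifier is a linear
soft-margin SVM evaluated by nested leave-one-out cross-validation:
the inner loop (LOO over the outer-training subjects) picks
C ∈ {0.1, 1, 10} by inner accuracy with ties resolved toward the
smallest C (strongest regularization); the outer model is refit on all
training subjects and scores the held-out one. Columns are z-scored
with training-fold statistics only — the held-out subject never
influences the scaling. With a single-element grid the inner loop is
skipped.

AUC is the Mann–Whitney pair statistic (ties counted half); the ROC
curve sweeps distinct score thresholds with tied scores grouped, so its
trapezoid area equals the pair-counting AUC exactly (asserted to
1e-10). Metrics with zero denominators are reported as undefined, never
silently 0. The permutation test reruns the entire nested procedure on
each of `n_perm` label permutations and uses the add-one estimator
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`, which cannot return 0
and is calibrated (null rejection rate ≈ α) in the acceptance tests.
The 2-D boundary export refits on the two channels with the largest
standardized mean difference (a documented convention; visualization
only) and reports a fresh LOOCV accuracy for that pair.

## Problem sizes used in the validation suite

Monte-Carlo checks use sizes chosen to keep the whole suite
desk-runnable while leaving comfortable statistical margins: estimator
anchors at N = 4096–8192 over 50 seeds; chance-level classification
over 100 permuted-noise datasets of 20 subjects; permutation-test
calibration over 200 null datasets (10 subjects, 4 features, 100
permutations, single-C grid); ANOVA type-I calibration at 2000 reps;
and the qualitative group-effect reproduction over 10 full-size default
cohorts (15 subjects × 2 sessions × 8 channels × 300 s). The
acceptance script runs one full cohort per design with a 200-permutation
significance test.

## Known limitations

* The suffix-R² onset rule cannot distinguish multiple scaling regimes
  and, at threshold 0.99, accepts near-power-law curves immediately;
  it is a selection convention, not a changepoint estimator.
* The log–log fit starts at k = 1 regardless of the detected onset, so
  small-scale bends bias absolute FD values (equally across groups in
  the synthetic cohorts).
* LOOCV on 15 subjects has high variance; the permutation p-value, not
  the point accuracy, is the meaningful significance statement.
* The generator makes no attempt at biophysical realism (no volume
  conduction, no artifacts, vestigial rhythms); it is an estimator and
  pipeline validation instrument.
* EDF support is read-only and requires the optional `mne` dependency;
  the native interchange format is matrix CSV with a YAML sidecar.
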