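# Methods

`betawatch` re-creates, offline and testable, an attention-monitoring
pipeline for low-cost single-channel EEG: one dry prefrontal (Fp1)
electrode per subject, sampled at 512 Hz in signed 12-bit vendor units,
with the beta band (12–30 Hz) as the sole attention marker. This note
documents the models, the defaults and why, and what the synthetic data
can and cannot show.

## Signal model and per-epoch chain

Vendor units convert to volts as

    V = raw · (1.8 / 4096) / 2000

(1.8 V input range, 4096-level ADC, amplifier gain 2000), i.e. one unit
≈ 0.2197 µV, and the signed range ±2048 spans ≈ ±450 µV. Converted
samples are clipped to the ±100 µV validation range before analysis (a
sample outside it is physiologically implausible for scalp EEG and the
artifact gate rejects the epoch anyway).

Analysis windows are non-overlapping 2-s epochs (1024 samples), cut on
an absolute sample grid by the transport emulator. Per epoch:

1. **Artifact gate.** Reject iff any |sample| strictly exceeds 75 µV.
   The gate runs on raw microvolts *before* filtering: a band-pass would
   smear a blink transient and could pull it under the threshold. 75 µV
   is the usual compromise between blink rejection and retaining
   high-amplitude cortical activity (literature spans 50–100 µV).
2. **Band-pass.** Butterworth order 4, 3–40 Hz, applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering is a deliberate divergence from
   any causal real-time implementation: it avoids group-delay distortion
   of epoch-aligned summaries. The band kills mains (50 Hz) and slow
   drift/flicker simultaneously; the squared-magnitude 50 Hz gain is
   ≈ 0.11 relative to mid-band.
3. **Detrend + z-score.** Linear detrend, then (x − mean)/sd. Z-scoring
   caps the leverage of any single energetic epoch on the session
   summary; a constant epoch cannot be z-scored and is rejected as
   degenerate rather than divided by zero.
4. **Welch PSD.** Tukey(0.15)-tapered segments of 256 samples (0.5 s,
   Δf = 2 Hz) at 50% overlap, one-sided density. Segment length is a
   package choice — the construction is specified only as "Welch with a
   Tukey window" — and 256 gives 7 averaged segments per epoch while
   still resolving the beta band into 10 bins. The taper is applied per
   segment, the standard Welch construction. With a single 1024-sample
   segment the estimator reduces exactly to one tapered periodogram
   (tested against a direct FFT oracle), and the integrated one-sided
   density of a z-scored epoch is ≈ 1 (Parseval, taper-corrected).
5. **Beta power.** Sum of PSD bins with centre frequency in the *closed*
   interval [12, 30] Hz times Δf. Half-open variants exist only for
   partition-additivity checks.

**Subject summary.** Only epochs lying fully inside video-labelled
segments count (the session timeline alternates 4-min videos with survey
and quiz blocks; attention is defined over the videos). The session
statistic is the **mean** of per-epoch beta power over accepted in-video
epochs. A sum variant is available (`epoch_aggregate="sum"`) because the
source description conflates "sum" and "mean"; the mean is the default
since artifact rejection leaves unequal epoch counts per subject and a
sum would confound attention with rejection rate. Across subjects the
totals are min–max scaled to the [0, 1] attention index; the scaling
spans the whole cohort. Subjects with zero accepted epochs are flagged
invalid and excluded from normalization with a warning.

## Transport emulation

One acquisition server instance admits at most four clients; a fifth
connection attempt is refused (a normal outcome, not an error). Packets
default to 512 samples (one second) but any size ≥ 1 works. Epochs sit
on the absolute sample grid, so a lost packet invalidates only the
window it interrupts: the partial window is discarded (logged), and
assembly realigns at the next epoch boundary. Dropping beats
zero-filling, which would silently bias the PSD downward. Missing-span
lengths are inferred from the nominal (first) packet size, exact for the
fixed-size transport emulated here.

## Statistics

**Correlation models.** Pearson, Spearman, and the skipped correlation.
The skipped estimator finds a robust bivariate centre with the minimum
covariance determinant (MCD), projects all points onto every direction
joining a data point to the centre, and flags a point whose projected
distance exceeds the boxplot-rule fence

    median + sqrt(chi²₀.₉₇₅(2)) · IQR

on any direction, with the IQR computed via ideal fourths; Spearman
(default; a Pearson basis is a flag) is then computed on the remainder.
The construction matches the robust-correlation toolbox lineage and is
verified point-for-point against an independent implementation in the
test suite. MCD subsampling is seeded, so the outlier set is
deterministic.

**CI and power.** 95% CIs are percentile bootstrap (default 2000
resamples, seeded). For the skipped model the outlier set is determined
once on the full sample and resamples are drawn from the cleaned pairs —
re-running the MCD search in every resample is two orders of magnitude
slower and changes nothing once gross outliers are removed; this is also
how the established robust-correlation tooling bootstraps skipped
estimates. The reported power is the post-hoc power of the two-sided
test at the observed r and effective n: critical r from the t
distribution (n − 2 df), observed effect through the bias-corrected
Fisher transform atanh(r) + r/(2(n − 1)), standard error 1/sqrt(n − 3).
Post-hoc power is a reporting convention, not an inferential quantity.

**Group analysis.** Subjects with scores within ±0.5 of the cohort mean
are excluded (neither clearly best nor worst); the rest split at the
pass mark (worst < 5 ≤ best); each group is trimmed to its own
[5th, 95th] beta-percentile interval (linear interpolation between order
statistics; trim applied per group). Shapiro–Wilk per group and Bartlett
across groups gate the test choice: only if all three p-values exceed
0.05 is a two-sample t-test used; otherwise the two-sided Mann–Whitney U
(exact enumeration when both groups have ≤ 8 untied values, midrank
normal approximation with tie correction otherwise). All tests
two-sided, α = 0.05. No multiplicity correction is applied across the
seven correlated variables, matching the analysis being reproduced.

## Classification

Features per subject: mean accepted beta power within each video segment
plus the session total, z-scored column-wise across the cohort (the
original platform does not state its classifier inputs; this is the
natural per-segment summary, and a total-only variant is a flag). Label:
pass iff score ≥ 5. The classifier is a small scikit-learn MLP validated
by leave-one-out: in each of n iterations the held-out subject plays no
role in either hyperparameter selection (grid search with inner
stratified k-fold, k = min(5, minority-class count) on the training
subjects) or fitting. Default grid: hidden layers {(4,), (8,), (8,4)},
L2 penalty {1e-4, 1e-3, 1e-2}, initial learning rate {1e-3, 1e-2}, Adam,
300 epochs, fixed seed. Pooled held-out probabilities give the ROC
(swept over all distinct cut-points), trapezoid AUC, and the confusion
matrix at threshold 0.5 with "pass" positive; metrics are reported to
two decimals in serialized reports, full precision in memory.

## Synthetic data: what it emulates, what it does not

Each trace is the sum of: 1/f-amplitude pink background (8 µV RMS),
band-limited Gaussian components (delta 6, theta 4, alpha 5 µV RMS;
beta per-subject), a 50 Hz sinusoid (2 µV), and Gaussian-windowed
biphasic blink pulses (derivative-of-Gaussian shape, peaks 100–200 µV,
width 0.25–0.45 s, Poisson arrivals at 0.05 Hz ≈ 3/min). Amplitudes
follow resting scalp EEG: composite background ≈ 12–25 µV RMS, beta
alone below 30 µV, blinks reliably above the 75 µV gate. A component
whose lone amplitude would clip more than 1% of vendor-range samples is
rejected with the component named. Quantization to integer units is
exact to half a step (≈ 0.11 µV).

Cohorts: per-subject beta RMS gain is log-normal (median 3 µV, 0.4
log-units). The task score shares a Gaussian copula with the beta gain:
the latent correlation a = 2 sin(π ρ_s/6) realises a requested Spearman
ρ_s; the latent maps affinely to the 0–10 scale (mean 5.0, sd 2.3,
matching a mid-difficulty task), plus independent score noise (sd 0.5),
clipped to [0, 10]. The six Likert mental-state answers are drawn
independently of beta gain with means/sds typical of a motivated
classroom (attention 4.3 ± 0.5, stress 1.7 ± 0.6, …), so their
correlations with measured beta are null by construction. The default
session timeline is the full study design — four 4-min videos each
followed by a 90-s survey and a 90-s quiz (28 min, of which the 16 video
minutes count).

Deliberately *not* emulated: true cortical dynamics (non-stationarity,
1/f knee, spindles), electrode impedance drift, inter-channel effects
(single channel only), movement artifacts other than blinks, and any
causal relation between attention fluctuations *within* a session and
momentary beta power — the association is imposed at the subject level.
A passing recovery suite therefore shows that the pipeline correctly
measures subject-level beta differences and preserves their association
with scores through every processing stage; it does not validate beta
power as a cognitive attention marker on real recordings.

## Problem sizes and numerical choices

The parameter-recovery suite runs 50 replicates of 200-subject cohorts
on a scaled session (two 16-s videos with 6-s question blocks) with
300-resample bootstraps — enough epochs (~16 per subject) for stable
beta estimates while keeping the suite at a few minutes. The acceptance
script replays the study scale instead: 34 subjects on the full 28-min
timeline with the full hyperparameter grid and 2000-resample bootstraps.
Unit and property tests pass reduced MLP grids through the public `grid`
argument. Other numerical conventions: strict inequality at the 75 µV
gate (a peak of exactly 75 µV passes); epoch-in-segment means both
half-open endpoints inside the segment; min–max normalization errors on
all-equal totals; constant correlation inputs error rather than return
NaN; seeds propagate explicitly (no global RNG state).

## Known limitations

- Reported headline numbers from the original 34-student experiment
  (skipped r = 0.53, group medians, AUC 0.82) depend on private data and
  are context, not reproduction targets; the package reproduces the
  *procedures* and validates them on known ground truth.
- The skipped CI underestimates outlier-detection variability slightly
  (outliers fixed across resamples; see above).
- Post-hoc power at the observed r is optimistic near large |r|.
- The MCD-based outlier rule can flag 1–3 points of a perfectly clean
  Gaussian cloud; this is a property of the boxplot fence, shared with
  reference implementations.
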