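# Methods

This note documents the models, estimators and design choices behind
`ppgcausal`, in the order the pipeline runs.

## Signal preprocessing

**Resampling and alignment.** Both channels are polyphase-resampled to
125 Hz.  PPG–ABP alignment maximizes normalized cross-correlation over
±2 s of lag; because quasi-periodic signals are ambiguous modulo their
period, correlations within 10⁻³ of the maximum are treated as tied and
the smallest |lag| wins.  Constant channels make alignment undefined —
the lag is reported as 0 with a warning.

**Denoising.** Stationary (undecimated) Daubechies-4 wavelet transform,
5 levels, universal soft threshold `σ_j √(2 ln n)` with `σ_j` from each
level's median absolute deviation, applied to the two finest detail
levels only (≳16 Hz at 125 Hz sampling).  Two deliberate departures
from the simplest textbook recipe, both forced by fiducial timing:
the decimated transform denoises pulse feet differently depending on
their phase relative to the dyadic grid (onset errors up to 9 samples
in testing), and thresholding the coarser, morphology-carrying levels
rounds the foot and systolic edges.  With this variant the
preprocessing chain recovers generated onsets within ±2 samples at the
default noise level.

**Onset detection.** Candidate upstrokes are maxima of the smoothed
first derivative at physiologic spacing (0.4–2.0 s).  The onset is the
maximum-curvature point (wide-stencil second difference) within ±6
samples of the preceding basin minimum — the foot's curvature spike is
a far sharper landmark than the basin minimum, whose position wobbles
under residual noise.

**Baseline correction.** A cubic spline through (onset, value) knots is
subtracted, so corrected onset values are ~0; with fewer than four
onsets the fit degrades to linear interpolation with a warning.

**Quality and plausibility.** SQI skewness and Pearson kurtosis
(Gaussian → 3) with configurable acceptance windows (defaults
skew ∈ [−3, 3], kurtosis ∈ [1, 10]).  Labels from ABP segments are
per-cycle medians: SBP the median systolic peak, DBP the median
cycle-boundary trough (≥3 cycles required); cuff-labelled records
carry their labels directly as one segment.  Plausibility rejects BP
outside 40–200 mmHg, pulse pressure < 10 mmHg, and segments whose
per-beat interval or amplitude z-score exceeds 3.0.  The z-score
dispersion is floored at 2% of the mean: metronome-regular synthetic
beats otherwise turn sub-sample jitter into huge z-scores.  Note the
z-screen has intrinsically bounded power on short segments (the
maximum possible z among m values is (m−1)/√m, so fewer than ~11 beats
can never exceed 3).

## Feature extraction (218 features)

Derivatives VPG–SPG are successive central differences, each preceded
by a 5-point moving average (4th derivatives are unusable without
smoothing).  Fiducials per beat: systolic peak, dicrotic notch,
diastolic peak on PPG; w/y/z on VPG; a–e waves on APG, found by
alternating prominence-gated extremum scans (gates at 2–5% of the
beat's derivative range reject residual-noise wiggles); the w search
skips the first 8% of the beat to avoid the foot transient.  Beats
missing core landmarks are skipped and logged; missing optional
landmarks yield NaN for the dependent features, the per-beat median
aggregation is NaN-aware, and any feature with no usable beat is 0.

The registry (`ppgcausal.registry`) pins names, order and category
counts: 3 frequency, 27 point-of-interest, 28 interval, 12 area,
21 cyclicality, 21 width, 2 SQI, 4 index, 25 deviation-curve and
75 histogram slots — 218 in total.  Within-category definitions that
the taxonomy leaves open are fixed in code and named transparently
(e.g. `sw50_norm` = systolic width at 50% amplitude over Tc;
`ipa_s4_s1` = S4/S1 area ratio; vascular indices
AgingIndex = (b−c−d−e)/a, I_bd = (b−d)/a, I_bcda = (b−c−d)/a,
I_sdoo = (s−d)/a with s the systolic PPG amplitude).  Temporal
features are Tc-normalized; the four segmental areas are reported as
fractions summing to one; histograms use 15 density-normalized bins
per signal over that signal's own range.

## Copula mutual information and CI testing

Marginals are mapped to normal scores `Φ⁻¹(rank/(n+1))` (average
ranks), making the MI estimate exactly invariant to monotone marginal
transforms.  MI is computed from determinants of the empirical score
covariance; conditioning uses I(X;Y|Z) = I(X;YZ) − I(X;Z).  No
small-sample bias correction is applied.  The CI decision refers
2n·CMI to χ²(1) (type-I error measured at 0.049 for nominal 0.05,
n=200); a permutation fallback exists for very small n.  Constant
columns are declared independent of everything.  For table-heavy
loops, `TableScores` rank-transforms each column once and caches the
full score covariance, so every CI test is a small-matrix determinant.

## Blanket discovery

**HITON-MB** ranks candidates by copula MI with the target (ties
lexicographic), admits greedily with interleaved backward elimination
over conditioning subsets of the current parents/children estimate
(max conditioning size 3), then recovers spouses: Y joins the blanket
iff Y ∈ PC(X) for some X ∈ PC(T), Y ∉ PC(T), and Y remains dependent
on T given its recorded separating set plus X.

**PPFS** orders candidates by marginal copula MI and admits a feature
when permuting its held-out column across 5 CV folds significantly
raises the MSE of a 5-NN regressor (standardized features) given the
features already selected — a one-sided paired t-test at α; a shrink
phase re-tests each selected feature given the rest.  Deterministic
for fixed seed (fold split and per-feature permutation streams are
seed-derived).

## Invariant selection across sources

The per-dataset ensemble blanket is HITON ∪ PPFS.  minMB is the
intersection across datasets *initialized to the first blanket* —
initializing to ∅ would make it trivially empty.  supMB features are
ranked by AMI; candidate subsets are enumerated largest-size-first
(prefix-biased toward top-AMI features; an ascending order is
available by flag), with a 50 000-subset budget and pruning of
supersets of subsets that failed in every dataset.  The final set is
minMB ∪ (first passing subset).

**Two significance levels.**  α = 0.05 everywhere a CI test decides
dependence.  The invariance screen, however, runs at
`alpha_invariance = 0.4`, and this is structural, not a tuning knob:
for a subset of m features in which exactly one feature's MI is
inflated by Δ in one dataset — the signature of a dataset-specific
spurious feature — the one-sample t-statistic of that dataset's
profile equals exactly 1, independent of m and Δ (mean shift Δ/m,
sample s.d. Δ/√m, s.e. Δ/m).  Any screening level below
P(|T| ≥ 1) ≈ 0.33 therefore can never reject single-feature
contamination, and the screen degenerates to accepting everything.
Genuinely invariant subsets sit near t = 0, because the denominator's
between-feature MI spread dwarfs the sampling noise of a dataset mean,
so they still pass comfortably at 0.4.  On the benchmark (below) the
0.05 screen admits every spurious feature; the 0.4 screen excludes
them in 20/20 seeds without losing blanket recall.

**Baselines.** Per-engine union/intersection across datasets (the
empty intersection is a legal, flagged outcome) and a random-forest
impurity-importance selector (importances normalized to sum 1,
selection above the mean).  Kendall tau-b matrices quantify
cross-dataset rank consistency.

## Estimation harness

Record-level splitting assigns whole subjects (leakage asserted zero
on every fold); sample-level assigns rows.  Default fractions
70/15/15; k = 5 folds.  Models: SVR (RBF, C=10, standardized inputs),
random forest and the two boosters (300 trees, depth ≤ 8, learning
rate 0.05), all single-threaded and seed-pinned for byte-level
reproducibility.  Metrics follow the printed conventions: ME is the
signed mean error; MAD the mean absolute difference; STD the
*uncentered* root-mean-square error (a config flag reports the
centered SDE alongside, since the AAMI definition is centered — for
near-zero ME the two coincide); MASE divides MAD by the MAD of a
predictor that always outputs the training-set median.  AAMI pass
means |ME| ≤ 5 and STD ≤ 8 mmHg (boundaries inclusive); IEEE 1708
pass means MAD ≤ 6 mmHg.

## Synthetic data: what it emulates and what it does not

**Waveforms.** A beat template — systolic Gaussian (amplitude 1.0 at
30% of the cycle, width 8%), dicrotic Gaussian (0.25 at 65%, width
10%) and an accelerating end-diastolic runoff 0.5(1−u)^0.25 — is
smoothed periodically and rolled so the maximum-curvature foot sits at
index 0.  Trains of identical beats get white noise (default s.d.
0.02 of the systolic amplitude) and sinusoidal baseline drift (0.1,
10 s period).  Ground-truth fiducials are obtained by running the
package's own fiducial definition on the noise-free template, so
recovery tests isolate noise-induced displacement.  Synthetic ABP
scales the same template so every cycle peak/trough equals SBP/DBP
exactly.  Not emulated: beat-to-beat morphology variability, motion
artifacts, arrhythmia, sensor saturation — passing tests demonstrate
correctness of the machinery, not field robustness on real
recordings.

**Fiducial timing resolution.** At the default noise level the
upstroke-side landmarks (onset, systolic peak, w, y, a, b) are
recovered within 1–2 samples; the dicrotic-region landmarks (notch,
diastolic peak, z) within ~2 and the late APG waves c/d/e only within
~5 samples — third/fourth-derivative extrema in a flat region are
intrinsically noise-limited.  Tests assert per-fiducial medians at
exactly these resolutions.

**Multi-source SCM.** K = 3 datasets of n = 1000.  Features start as
independent standard normals; the target mechanism is shared across
datasets: M = 0.8 f00 + 0.8 f01 + 0.6 f02 + 0.3 (f02² − 1) + ε(0.8)
(one partly quadratic parent exercises the estimator's monotone-
nonlinear reach), child f03 = 0.8 M_std + 0.7 f04 + ε(0.6) with
spouse f04; the blanket is {f00…f04}.  Each dataset carries one
spurious feature built as ρ·M_std + √(1−ρ²)·noise *in that dataset
only*, with heterogeneous strengths ρ = 0.70/0.50/0.35 — sources
differing in confounding severity.  Mild per-dataset affine shifts of
the features emulate device/population heterogeneity (rank-based
dependence is unaffected).  The target is reported on an SBP-like
scale, 120 + 12·M_std mmHg.  Subject labels cycle over 50 subjects per
dataset with no subject-level random effect, so record-level splitting
carries no penalty in the synthetic benchmark.

**Benchmark scales.** The selection benchmark uses 20 seeds at the
sizes above; blanket-recovery checks use the 8-node linear-Gaussian
graph at n = 3000 (20 seeds, against an exhaustive-CI oracle whose
spouse candidates are restricted to the exhaustive parents/children of
a common child) and a two-parent design at n = 500 for PPFS.  The
end-to-end determinism check runs the full waveform-to-report pipeline
twice on two datasets of 55 records each.

## Known limitations

- The invariance screen tests dataset-level *mean* shifts of the MI
  profile; it cannot detect a spurious feature whose own-dataset MI is
  matched by symmetric contamination of the other datasets (profiles
  with equal means pass by construction).  The heterogeneous-strength
  benchmark reflects the realistic asymmetric case.
- The one-sample t-test treats per-feature MI values as exchangeable
  draws, which is wrong in distribution (MI estimates differ in scale
  and are dependent); the screen is a heuristic decision rule, not a
  calibrated test.
- HITON's conditioning is capped at size 3; dense true graphs with
  larger separating sets will leak false positives.
- Feature definitions within taxonomy categories follow this package's
  registry; other PPG pipelines allocate the same category budgets
  differently, so absolute feature indices are not comparable across
  toolkits.
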