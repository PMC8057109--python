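# Methods

`ctgscreen` implements a screening analysis that discriminates healthy
from late-growth-restricted (late IUGR) fetuses using quantitative
features of antepartum cardiotocographic (CTG) fetal heart rate (FHR)
recordings: 2-Hz FHR in bpm with a tri-level per-sample quality flag and
an optional uterine-activity channel. This note documents the models,
the parameter choices that matter, what the synthetic cohort generator
does and does not emulate, and the numerical conventions.

## Signal model and preprocessing

Recordings are segmented into non-overlapping 1-min (120-sample) and
3-min (360-sample) epochs starting at sample 0; a trailing remainder is
dropped. An epoch is discarded when it contains more than five
consecutive insufficient-quality ("red") samples or when its red count
reaches 5% of the window (6 of 120, 18 of 360). The boundary is read as
*reject at exactly 6 (18)*: "more than 5%" and "6 out of 120" are
mutually inconsistent (6/120 is exactly 5%), and the operational counts
are taken as authoritative. Isolated red samples — runs of length 1 —
are replaced by the mean of the five nearest non-insufficient samples
(absolute index distance, ties toward earlier samples) and upgraded to
acceptable quality; longer runs are left to epoch rejection. Repaired
samples are counted against the 5% budget *before* repair. Subjects
with fewer than 30 usable 1-min epochs or fewer than 10 usable 3-min
epochs are excluded.

## Morphological and time-domain features

The FHR **baseline** is a per-sample estimate from an iterative trimmed
low-pass procedure in the Mantel style: second-order zero-phase
Butterworth low-pass (cut-off 0.0012 Hz), seed at the dominant 1-bpm
histogram mode of the filtered trace, then repeat { exclude samples
deviating > 20 bpm from the current baseline, bridge them by linear
interpolation, re-filter } until the estimate moves < 1 bpm everywhere
or 10 iterations. The cut-off is deliberately stiff: a single 20-bpm,
20-s acceleration — which the 20-bpm trim rule cannot exclude — must
lift the baseline by less than 1 bpm.

**Events.** A candidate event is a run of samples whose excursion from
baseline exceeds a 5-bpm onset threshold for at least 15 s (30
samples), classified by peak excursion: large acceleration >= 15 bpm,
small acceleration 10–15 bpm (the lower bound is a declared choice; the
clinical rule only says "fewer than 15"), deceleration with peak depth
>= 15 bpm. Classification by *peak* follows clinical practice, where an
acceleration is an excursion reaching 15 bpm and lasting 15 s, not one
staying above 15 bpm for 15 s. Uterine contractions are runs of the
uterine channel at least 30% above its rolling 10-min median tone
lasting >= 30 s; these detector constants are implementation-defined.
Counts are per recording; a missing uterine channel reports the
contraction count as missing, not zero.

**Variability indices** are computed on the classical
24-cells-per-minute beat-interval series: per 2.5-s cell (5 samples)
the mean of 60000/FHR in ms. Cells overlapping unusable 1-min epochs
or detected acceleration/deceleration events are dropped. Per usable
minute (>= 12 valid cells): STV = mean |successive cell difference|,
II = STV / SD of the minute's cells, Delta = max − min; each averaged
over minutes. LTI = per 3-min window, the interquartile range of
m(j) = sqrt(t24(j)² + t24(j+1)²) over valid adjacent pairs, averaged
over windows. A constant signal yields STV = Delta = LTI = 0 and an
undefined (missing) II.

## Frequency-domain features

Per usable 3-min epoch the power spectral density of the per-sample
beat-interval signal (60000/FHR, ms domain, at the full 2 Hz) is
modelled by an AR(12) process fitted with the Levinson–Durbin recursion
on the biased autocorrelation of the linearly detrended epoch. The ms
sample series — not the 24-cell/min series — feeds the spectrum because
the HF band extends to 1 Hz, the Nyquist frequency of the 2-Hz trace; a
0.4-Hz cell series cannot support it. Band powers come from the
pole-residue decomposition of the AR spectrum: each pole p_k
contributes a component at central frequency |arg p_k|/2π · fs with
power equal to the residue of S(z)/z at p_k (conjugate pairs combined
as 2 Re), assigned to LF (0.03–0.15 Hz), MF (0.15–0.5 Hz) or
HF (0.5–1 Hz) by central frequency. Components centred below 0.03 Hz
are excluded from all bands; the component powers sum to the process
variance. Consequences worth knowing: band powers can differ from
numerical band integration when components are broad (Lorentzian tails
leak across band edges — the two routes agree within 5% only for
narrowband components), and on flat spectra the LF estimate sits
slightly low because sub-0.03-Hz components absorb nearby mass. The AR
order (12) is a mid-range convention, configurable; a constant epoch is
flagged degenerate with zero band powers; an unstable model raises an
error suggesting order reduction.

## Complexity-domain features

Per 3-min epoch, on the bpm signal:

* **ApEn** (m = 1, r = 0.1 × epoch SD, self-matches included) and
  **SampEn** (self-matches excluded, −ln(A/B)). The tolerance "0.1" is
  interpreted relative to the epoch SD, the field convention. SampEn
  with no matching template pairs is missing, never infinite; a
  zero-variance epoch gives 0 for both.
* **LZC** of the sign-symbolized difference signal with threshold
  factor p = 0: binary (d > 0) or ternary (sign d, exact zeros are the
  middle symbol — frequent and intended for quantized monitor output).
  Phrases are counted by Lempel–Ziv 1976 exhaustive-history parsing and
  normalized as c(n) · log_α(n)/n. The normalized value is invariant to
  monotone rescaling of the signal.

**PRSA** runs once over the whole repaired recording (bpm domain):
windows of L = 100 samples cannot sit usefully inside 360-sample
epochs without severe edge loss. Anchors are points where the mean of
the T samples starting at i strictly exceeds (acceleration) or falls
below (deceleration) the mean of the T samples before i; anchors
within L of either edge are skipped; windows [i−L, i+L) are averaged
pointwise. The capacity at scale s is the Haar contrast
[Σ_{k=0..s−1} x(k) − Σ_{k=−s..−1} x(k)] / 2s: AC from acceleration
anchors, DC (negative by construction) from deceleration anchors,
DR = AC + DC. The four (T, s) pairs are (1,2), (5,5), (9,9), (40,1).

## Feature table

The registry holds exactly 32 features: 10 morphological/time, 3
frequency, 16 complexity, 3 fetal–maternal (gestational age at the
recording, fetal sex encoded male = 1 / female = 0, maternal age).
Epoch-level features are averaged over usable epochs per subject;
subjects with any feature entirely missing are dropped. The cohort
table is then Winsorized per feature to (Q1 − 3·IQR, Q3 + 3·IQR)
(linear-interpolation quartiles; a zero-IQR feature collapses the
fence to the quartiles, leaving a constant column unchanged) and
z-scored with the n−1 variance denominator. Standardization is over
the entire population by default — a deliberate, known leakage choice
matching the procedure being reproduced; `standardize(fit_on=...)`
provides the leakage-free train-only alternative. Winsorization is
applied after aggregation, at the subject level.

## Univariate benchmark

Each feature alone is scored by an unpenalized logistic model (score =
fitted probability; monotone in the feature, so the ROC equals the raw
feature's ROC, which is asserted in tests). The ROC uses all observed
thresholds, orientation auto-chosen so AUC >= 0.5, AUC by the
trapezoidal rule; the operating point maximizes Youden's
J = SE + SP − 1, ties broken toward higher sensitivity (IUGR is the
positive class; the tool is a screener). The correlation screen flags
feature pairs at |Pearson ρ| >= 0.7 (configurable).

## RBF-SVM, feature elimination, tuning, evaluation

The classifier is a soft-margin SVM with Gaussian kernel
K(x, z) = exp(−γ‖x − z‖²) (sklearn's dual solver; KKT tolerance 1e-3).

**RFE.** Features are ranked by recursive elimination using the
first-order Maclaurin expansion of the kernel: with a_i = α_i y_i from
the current fit, score(j) = |γ Σ_{i,k} a_i a_k (x_ij − x_kj)²|,
computed in O(n·d) via 2[(Σa)(Σa x²) − (Σa x)²]. The minimum-score
feature is eliminated (ties by registry order), the model refit at the
fixed provisional (C, γ) = (1, 1/n_features), and the cross-validated
J of every subset along the path recorded; the selected subset is the
smallest attaining the maximal mean CV J (parsimony at equal
performance). A frozen-α kernel-perturbation score ΔJ(j) =
½|αᵀHα − αᵀH^(−j)α| serves as an independent cross-check of the
ranking; the two agree (Spearman >= 0.8) in the small-γ regime where
the first-order expansion is valid. Known limitation: like all
squared-weight RFE variants, correlated features share weight and may
be eliminated before weaker independent ones; with redundant signals
the CV-J path peaks at compact subsets, so redundant informative
features are often pruned rather than retained.

**Grid search.** C = γ = 2^−15 … 2^15 (31 × 31 = 961 cells; a
coarsened 11 × 11 grid with exponent step 3 is the scaled-down default
for desk-size runs). Each cell is scored by stratified 10-fold CV
(repeated 5× during search at full scale, 2× in the scaled-down
configuration) with mean J as the figure of merit; ties prefer higher
SE, then smaller C. Maximizing J with an SE tie-break reconciles the
two stated objectives (J maximization and SE as screening figure of
merit): at the reproduced optimum they coincide.

**Evaluation.** The cohort is split 60/40 stratified by class (seeded).
Training metrics are means with normal-approximation 95% CIs over the
fold-level values of a 10-fold × 10-repeat CV on the training set; test
metrics (accuracy with a Wald CI, SE, SP, PPV, NPV, AUC from the
decision function) come from a single fit on the full training set
applied to the untouched test subjects. Leave-one-feature-out
importance retrains the CV with each selected feature excluded and
reports the paired fold-level decrease in accuracy/SE/SP with CIs. A
fetal-sex-excluded variant drops `fetal_sex` before selection,
leaving 31 features.

## Synthetic cohort generator

The generator exists so the entire analysis runs end-to-end with no
external data; it emulates the *statistical structure the analysis
assumes*, not fetal physiology. Per subject: FHR = class baseline
(healthy 140 ± 8 bpm across subjects, IUGR 142 ± 8) + slow wander
(3 bpm SD below 0.008 Hz) + band-limited Gaussian noise from order-4
Butterworth bandpasses at the three analysis bands (healthy SDs
6.0/2.0/1.2 bpm for LF/MF/HF, IUGR 4.5/1.5/0.7; per-subject lognormal
amplitude spread 0.35) + Poisson accelerations (healthy 8 per 40 min,
IUGR 3.5; flat-topped raised-cosine (Tukey) profile, 20 bpm / 20 s
defaults, so a default event is detectable under the 15-s duration
rule) and rare decelerations (0.5 vs 1.0 per 40 min), quantized to
0.25 bpm. The uterine channel is a 20-a.u. tone plus Gaussian
contraction waves (3 per 40 min, both classes). Quality flags follow a
two-state burst model (0.002 starts/sample; 60% isolated points,
otherwise geometric runs of mean 4), which leaves the large majority
of subjects above the inclusion thresholds. Metadata are drawn per
class from the reference populations: GA 37.54 ± 0.77 vs 36.94 ± 0.59
weeks, male fraction 0.55 vs 0.4608, maternal age 32.2 ± 5.2 vs
32.4 ± 5.8 years; default cohort 160 healthy / 102 IUGR. Every knob is
config-exposed; the class-parameter values above are the fixed study
conditions of the test suite.

The IUGR defaults lower short-term variability, HF power, large-
acceleration counts and binary-LZC irregularity — the directions the
analysis should recover. A direction oracle reports the sign of each
feature's expected class difference for parameter-recovery tests; it
claims no direction for ternary LZC: at 0.25-bpm quantization the
smoother IUGR traces gain interspersed zero-difference symbols that can
*raise* ternary phrase diversity, so that feature is not monotone in
the generator knobs. What passing tests show is that the pipeline
recovers structure of this known generative form; real FHR exhibits
state switching (quiet/active sleep), nonstationarity, circadian and
gestational-age trends, and monitor artifacts none of which are
emulated, so synthetic performance figures say nothing quantitative
about clinical performance.

## Numerical conventions and degenerate inputs

0-based sample indexing throughout; 2 Hz is fixed. Quartiles use
linear interpolation; variances use n−1 unless noted (epoch SD for
entropy tolerances uses the population form). Zero-SD features
standardize to 0 with a warning. Constant signals: baseline is the
constant itself, no events, zero variability indices, degenerate AR
model, zero entropies, minimal LZC, no PRSA anchors (strict
inequality), missing capacities. Seeds propagate through
`numpy.random.SeedSequence` spawning, so cohorts are bit-reproducible
per seed, and every CV split is seeded.

## Problem sizes used in the shipped checks

The automated checks run the full default cohort (262 subjects,
40-min records) for the pipeline-level properties, the coarsened
11 × 11 grid with 10-fold × 2 CV in place of the full
31 × 31 × 10-fold × 5 search, 10–20 generator seeds for
parameter-recovery statements, and small constructed tables for
importance contrasts; these sizes are the package's chosen study
conditions for desk-scale reproduction.
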