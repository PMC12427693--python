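# Methods

This note records the models, estimator conventions and design choices
behind `eegdx`, in the spirit of the methods documentation of statsmodels
or msprime: enough detail that every number the package produces can be
traced to a definition.

## Signal model of the synthetic cohorts

Each synthetic subject's channel signal is the sum of three independent
sources:

1. **Oscillators** — sinusoids `a·sin(2πft + φ)` restricted to target
   channels, with the phase φ drawn once per subject from the seeded
   generator. These stand in for rhythmic EEG components (posterior alpha,
   frontal beta, diffuse theta).
2. **Aperiodic background** — white Gaussian noise shaped in the frequency
   domain to a `1/f^a` power profile (amplitude `f^(−a/2)`, DC removed,
   renormalized to unit SD) and scaled by an `irregularity` factor. The
   exponent `a` controls the spectral slope, the stylized correlate of
   cortical excitation/inhibition balance; `irregularity` controls the
   noise-to-oscillation ratio and hence every entropy/complexity feature.
3. **Mains** — a 50 Hz sinusoid at a configurable relative amplitude
   (default 0.2), present so the notch stage is exercised end to end.

The five default group profiles mirror the study population's sizes
(43 control / 28 depression / 40 Alzheimer / 42 schizophrenia / 28 MCI)
and encode stylized, deliberately strong contrasts: slowed and attenuated
posterior alpha with a steeper slope (a = 1.4) and reduced irregularity
(0.6) in Alzheimer's; an intermediate version for MCI (8.5 Hz, a = 1.2,
0.8); frontal alpha excess in depression; flattened slope (a = 0.8),
raised irregularity (1.4) and weak alpha in schizophrenia. No published
per-group EEG effect sizes exist at this granularity, so these profiles
are calibration knobs chosen once to make group structure clearly
recoverable; they are not estimates of any clinical cohort. Consequences:
passing pipeline tests demonstrate that the machinery recovers structure
that is present, not that clinical effect sizes of this magnitude exist.
Real EEG features the generator does not emulate: eye-blink and EMG
artifacts, inter-channel correlation from volume conduction,
non-stationarity (eyes-open/closed alternation), and drowsiness drift.

Default recording length is 120 s — the minimum giving two 60-s windows
for the long-window statistics — at 500 Hz on the standard 19-channel
10–20 montage (Fp1 … Pz). Per-subject seeds are spawned from the cohort
seed via `numpy` SeedSequence, so cohorts are bit-reproducible.

## Preprocessing

Order of operations: per-channel min–max normalization to [0, 1], then a
50 Hz notch, then a 1–30 Hz band-pass. Settings:

* **Notch**: second-order IIR notch, quality factor Q = 30, applied
  forward–backward (zero phase). Q = 30 rejects > 20 dB at 50 Hz while
  leaving 48/52 Hz essentially untouched.
* **Band-pass**: Butterworth of order 4, forward–backward via
  second-order sections. The effective order-8 magnitude response meets
  the contracts asserted in the tests: ≥ 20 dB attenuation at DC and
  50 Hz, ≤ 1 dB ripple at 10 Hz, at both 250 and 500 Hz sampling.
* **Degenerate channels**: a constant channel normalizes to all-0.5 with
  a warning rather than dividing by zero; it then filters to ≈ 0.

Filtering is linear, so normalization before filtering only affects
offset and scale, but the order is fixed as above and recordings carry a
`preprocessed` flag; preprocessing twice is refused.

## Feature battery — conventions

All windowed features use non-overlapping 2-s (1000-sample) windows with
trailing partial windows dropped; aggregation across windows is the mean
and the (population) variance. The 34-per-channel layout `paper34` is:
2 full-signal spectral summaries + 15 windowed measures × 2 statistics +
kurtosis/skewness means over non-overlapping 60-s windows. An `extended`
layout adds whole-signal Hjorth parameters (37 per channel) for analyses
that want them; it is not the default because the default layout is the
one whose total is 646.

* **Welch PSD**: 512-sample Hann segments, 50% overlap; inputs shorter
  than one segment fall back to a single-segment periodogram with a
  warning. Frequency resolution fs/512.
* **freqmax/powmax**: argmax of the full-signal PSD; ties resolve to the
  lower frequency.
* **SEF50**: smallest frequency at which the cumulative in-band
  (1–30 Hz) power reaches 50% of the in-band total.
* **Spectral entropy**: `−Σ Fᵢ ln Fᵢ` with `Fᵢ` the in-band PSD
  normalized to sum 1; zeros guarded by ε = 1e-12. Natural log, so the
  maximum is ln(number of in-band bins).
* **Dyadic spectral entropy**: same formula on the five octave-band
  energies {1–2, 2–4, 4–8, 8–16, 16–30} Hz; range [0, ln 5]. These are
  the only dyadic levels inside the 1–30 Hz passband.
* **ApEn**: classic formulation, m = 2, r = 0.25 × sample SD (ddof = 1)
  of the window, Chebyshev distance, self-matches included,
  `Φ_m − Φ_{m+1}` with `Φ_m` the mean log match fraction. A constant
  window returns 0 with a warning.
* **Log-energy entropy**: `Σ ln(xᵢ² + ε)`.
* **Permutation entropy**: order m = 6, lag 1 by default; ordinal
  patterns from a stable argsort (ties broken by index order); Shannon
  entropy in bits normalized by log₂(m!) so equiprobable patterns give
  exactly 1. Note that m = 6 on 1000-sample windows is undersampled
  (720 possible patterns vs 995 motifs), which biases the value down;
  the default is kept as the method's operating point and the limiting
  behavior is verified at m = 3.
* **Rényi (α = 2) and Tsallis (q = 2) entropies**: computed on a
  32-bin amplitude histogram of the window (≈ √N bins at N = 1000).
  Rényi: `(1/(1−α)) log₂ Σ pᵢ^α` (bits). Tsallis: `Σ(pᵢ − pᵢ^q)/(q−1)`.
  The histogram bin count is the probability-estimation knob; 32 keeps
  the estimates stable at this window length.
* **Hjorth**: activity = var(x), mobility = √(var(Δx)/var(x)),
  complexity = mobility(Δx)/mobility(x), with Δ the first difference and
  population variances. A sampled pure sinusoid gives complexity exactly
  1 (the parameter's reference value); degenerate variances yield zeros.
* **LZ76 (`lempel`)**: the signal is binarized at its median
  (x > median → 1), then parsed by the exhaustive-history rule — a new
  phrase starts whenever the current substring cannot be copied from the
  prior history; the final incomplete phrase counts. The raw phrase
  count c(n) is the feature. An all-constant window parses to c = 2.
* **Kolmogorov proxy**: Kaspar–Schuster normalization `c(n)·log₂(n)/n`
  of the same parse — near 1 for random binary strings, → 0 for regular
  ones. Kolmogorov complexity proper is uncomputable; this normalized
  LZ76 value is the standard surrogate and is correlated with `lempel`
  by construction.
* **Kurtosis/skewness**: standardized fourth (non-excess, Pearson) and
  third central moments, biased (n-denominator) form; zero-variance
  windows yield 0 by convention.

Feature names follow `channel__feature__stat`
(`F7__ApEn__mean`, `Pz__skew__mean60`); the two full-signal spectral
summaries are `channel__feature`. 19 × 34 = 646 columns in a fixed
lexicographic-by-(channel, feature, stat) order.

## Lasso selection

The selector fits an ℓ1-penalized logistic deviance; the classification
objective is the natural reading of "a linear classifier's coefficient"
for a diagnostic task. sklearn's `LogisticRegression` is the solver, with
the shrinkage weight mapped as C = 1/(n·λ) so λ matches the
mean-deviance + λ·‖β‖₁ parameterization used by MATLAB-style lasso
implementations. Features are standardized before fitting (selection
should not depend on per-feature units; an unstandardized mode exists
and the tests demonstrate it changes the support). λ is chosen from 25
log-spaced values on [0.001, 0.05] by stratified 10-fold CV
misclassification loss; ties resolve to the smaller λ (less shrinkage
among equal losses). For more than two classes the default is
one-vs-rest fits whose supports are unioned; a multinomial ℓ1 fit (saga)
is available by configuration. Coefficients below 1e-6 in magnitude
count as zero.

**Leakage caveat**: the default `paper` protocol performs selection once
on the full task data before classifier CV, replicating the original
analysis workflow; this optimistically biases CV estimates. A `nested`
protocol that refits selection inside each training fold is provided and
reports label which was used.

## Group statistics

Per feature: Shapiro–Wilk at α = 0.05 in every group routes to one-way
ANOVA + Tukey HSD (all groups normal-looking, none degenerate) or to
Kruskal–Wallis + Dunn's z-tests with Bonferroni correction (adjusted
p = min(1, raw × number of pairs)). Routing per feature, rather than
running both families, yields a single post hoc table per feature. A
zero-variance group forces the nonparametric route with a warning.
Dunn's test uses tie-corrected rank variance; for two groups its z² is
identical to the Kruskal–Wallis H, which the tests exploit as an exact
cross-check. The package reports the per-feature long table plus summary
counts (features with omnibus p < 0.05; how often each group appears in
a significant pair).

## Classification and evaluation

Stratified 10-fold CV (per-class proportions within one member of the
global proportion per fold); k is reduced with a warning when the
smallest class has fewer members than k. Inside each fold, features are
standardized with training statistics only. Families: RBF-kernel SVM,
LDA (lsqr solver with shrinkage — necessary when features outnumber
subjects), a single-hidden-layer MLP with early stopping, and a random
forest. All stochastic components derive from one run-level seed, so
results are bit-reproducible.

Metrics come from the fold confusion matrix: accuracy, sensitivity,
specificity, precision, F-score; AUC from class scores (probabilities,
or softmax-mapped decision values for the margin-based SVM). Binary
tasks take the disease as the positive class (versus control) or the
first-listed class otherwise; multiclass metrics are macro one-vs-rest
averages, matching the single-number summaries such analyses report.
Zero-denominator metrics (e.g. precision of a never-predicted class)
report 0 with a warning. Per-fold tables, mean ± SD, and the aggregated
confusion matrix are all retained.

Hyperparameter tuning, when requested, is a seeded Bayesian optimizer:
a Matérn-kernel Gaussian-process surrogate with expected-improvement
acquisition over per-family boxes (SVM: log C ∈ [−2,3], log γ ∈ [−5,0];
LDA: shrinkage ∈ [0,1]; MLP: width ∈ {8…128}, log α ∈ [−5,−1]; RF:
trees ∈ [50,400], depth ∈ [2,20], features-per-split ∈ [0.05,1]),
objective = mean accuracy under an inner stratified 3-fold CV. A budget
of 1 returns the documented family defaults.

## Pipeline

`run_pipeline` chains the stages from one config and writes a bundle:
feature matrix CSV (+ parameter sidecar), statistics tables, per-pairing
selection JSON/CSV, per-model CV tables and confusion matrices, and a
run manifest with SHA-256 hashes of every output — re-running the same
config reproduces the hashes. Pairings may be any subset of the group
labels plus merged classes (e.g. cognitive decline = Alzheimer + MCI).
Stage failures propagate wrapped with the stage name.

## Problem sizes used by the test suite

The suite exercises the full chain on deliberately small cohorts chosen
as the smallest sizes at which each property is meaningful: 3 groups ×
10 subjects × 120 s for the classification-recovery checks (10 per
class is the minimum for stratified 10-fold CV), 2 groups × 3 subjects
for pipeline plumbing, and 40 subjects/group at the feature-matrix level
for the selection-recovery checks. Statistical error-control simulations
use 200 null replicates.

## Known limitations

* The 34-feature layout is one consistent reading of a feature count
  whose published description is internally ambiguous; alternative
  compositions (e.g. whole-signal Hjorth) are exposed as layouts rather
  than silently substituted.
* Permutation entropy at the default order 6 is undersampled on 2-s
  windows (see above).
* The Rényi/Tsallis histogram estimator is a simple density proxy; no
  bias correction is applied.
* Synthetic profiles encode stylized group differences only; nothing
  here validates clinical discriminability of real cohorts.
* The `paper` protocol's selection-before-CV is optimistically biased by
  design (it replicates the original workflow); use `nested` for honest
  generalization estimates.
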