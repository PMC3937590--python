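# Methods

This note documents the models, defaults and numerical choices behind
responsekit, and what the synthetic benchmarks do and do not establish.

## Dose-response processing

A plate record carries two background ODs, an untreated triplicate, a 9 × 3
treated OD grid, time-zero (T0) plate readings and nine ascending
concentrations. Background correction subtracts the mean of the same-plate
background wells; triplicates are summarized by the median (robust to single
well failures); a concentration whose three replicates are all missing is
excluded with a warning, and a plate whose corrected control signal is ≤ 0 is
rejected. Percent growth uses the two-branch convention (net growth relative
to the control's net growth when the treated signal exceeds T0, net kill
relative to T0 otherwise): it is continuous at T = T0, equals 100 for an
untreated-like well and is clamped at −100 (complete kill), with the clamp
also guarding the bound against floating-point rounding.

GI50 (growth = 50) and TGI (growth = 0) are found by linear interpolation in
log10(concentration) over the first bracketing interval from the
low-concentration side, and stored as −log10(molar) so that larger values
mean more potent. A curve that never reaches the level is censored at the
highest tested concentration (`at_max`); a curve already at or below the
level at the lowest concentration is censored there (`at_min`). Censoring
flags are carried through the response matrix because off-scale measures
still carry ordering information but should not be mistaken for interior
estimates. Replicate plates of a (line, compound) pair are combined by the
median GI50; the flag is kept only when all replicates agree. The
per-compound dynamic range is max − min of −log10 GI50 over lines with
unclamped values.

The low-variation filter retains compounds with an SD of −log10 GI50 of at
least `sd_floor` (default 0.25 log10 units) and an off-scale fraction of at
most `offscale_max_fraction` (default 0.5). The defaults describe a compound
whose response spread is comfortably larger than the plate-level measurement
noise; both are configurable because the appropriate floor depends on assay
noise.

No parametric (Hill/4PL) curve fit is attempted: the piecewise-log-linear
crossing is assumption-light, exactly invertible by the synthetic generator,
and adequate for the 9-point design.

## Labels

Per compound, the dichotomization threshold is the arithmetic mean of
−log10 GI50 over the core line set — lines with response data and at least
four molecular data sets (`core_line_set`). All lines with a GI50 are then
labeled against that threshold, sensitive strictly above it. A line exactly
at the threshold is resistant: the conservative tie rule (do not recommend a
borderline compound), also used when a predicted probability sits exactly at
a decision threshold. A single-class labeling is flagged unusable rather
than silently trained on.

## Classifiers

**Weighted LS-SVM.** Training solves the (N+1) × (N+1) saddle system in the
dual variables; the implementation is a dense symmetric solve with one ridge
jitter (1e−8 on the regularized Gram diagonal) retried on singularity.
Class-balancing weights w_i = N / (2 N_class) give each class equal total
loss weight, the standard correction for the moderate imbalance that mean
thresholding produces. Kernels: linear (default at n ≈ 48 ≪ p) and radial.
Decision values are mapped to probabilities by a two-parameter sigmoid
(Platt scaling) fitted on training decision values; the toolbox consumes
probabilities, while raw decision values are used for AUC (which only needs
ranks). The dual solution is checked against an independent least-squares
solve of the same system in the test suite and the acceptance script
(≤ 1e−8 relative difference on random instances up to N = 30).

**Grid search.** Features are ranked by absolute Welch t statistic computed
inside each inner-CV training fold; the grid spans feature counts
k ∈ {25, 50, 100, 200, 400} × γ ∈ {0.1, 1, 10} by default, selected by mean
inner-fold AUC with ties resolved toward the smallest k, then the smallest
γ. The lower bound of 25 reflects the realistic size range of published
multi-gene response signatures (tens to a couple of hundred features);
starting the grid at very small k would let exact inner-AUC ties collapse
strong signatures to a handful of features. The ranking statistic is
configurable in spirit (any score producing a feature ordering slots in),
but the t statistic is the default because it matches the per-gene reduction
step.

**Best feature per gene.** Multi-level transcriptome data (gene, transcript,
exon, junction, boundary, intron) can be reduced to the single feature per
gene with the largest |t| against the labels. This step is supervised, so it
belongs inside training folds only; applying it before splitting would leak
test labels into feature choice and bias the multi-split AUC upward.

**Random forest.** scikit-learn's classifier with 1000 trees and
mtry = √p by default; probability = fraction of trees voting sensitive;
importances are exported for signature reporting. Deterministic per seed.

**Evaluation.** Repeated stratified divisions into 2/3 training and 1/3 test
(default 100 splits; the benchmarks below use 15–20 to keep runtimes in
seconds at no material loss for the questions asked). Standardization
parameters, feature ranking, grid search and calibration are all refit on
each training fold. Continuous features are standardized; binary (0/1)
columns such as mutation indicators are passed through unscaled. A leakage
canary in the test suite verifies that a feature made perfectly informative
on test rows only is not preferentially selected.

On finite null panels the mean test AUC across splits is not exactly 0.5 per
dataset: the labels' spurious correlations with the 1000 features are fixed
per panel, so dataset-level deviations of roughly ±0.07 SD remain no matter
how many splits are averaged, with a slight downward skew (features selected
for an overestimated training correlation tend to anticorrelate on the
held-out third of the same panel). This is a property of multi-split
evaluation at n = 48 with aggressive feature selection, not an
implementation artifact; it is why the null-calibration check asks for the
band [0.4, 0.6] rather than a tight interval around 0.5.

## Data-type comparison

Per (compound, data type) the best AUC is the max over methods (and
gene-level vs all-feature variants where applicable). Ranking uses the mean
best AUC; the overall difference is tested by a classical one-way
repeated-measures ANOVA with compounds as subjects (statsmodels AnovaRM on
complete rows), and all pairwise differences by paired t tests with
Benjamini-Hochberg adjustment (the FDR-flavored correction consistent with
the rest of the pipeline). A constant non-zero paired difference has no
within-pair variance; it is reported as infinitely significant (p = 0)
rather than undefined, and identical columns as p = 1. Comparisons should be
run on the line intersection common to the requested data types; excluding
normal-like lines is a config flag.

A compound is `subtype_sufficient` when the subtype-only baseline (one-hot
subtype + ERBB2 flag, same multi-split protocol) exceeds AUC 0.7 and the
best omics model adds less than 0.1; `omics_adds` when the best model
exceeds 0.7 with a gain of at least 0.1 (boundary gains of exactly 0.1 count
as gains, with a 1e−9 tolerance absorbing float subtraction); otherwise
`weak`.

## Patient toolbox

Applying a signature standardizes tumor features with the training-panel
means/SDs stored in the signature. Missing signature features are imputed at
the training mean (standardized 0) — neutral by construction — but only up
to 20% per data type; below 80% overlap the signature refuses to predict
rather than extrapolate.

Cutoff selection fits 1-, 2- and 3-component Gaussian mixtures by EM
(5 restarts, seeded) and picks the count by BIC. Cutoffs sit at the density
intersections of adjacent components, solved in closed form from the
quadratic equality of two weighted normal densities (midpoint fallback if no
root lies between the means). With two components the single intersection
separates intermediate from sensitive, and the resistant boundary falls at a
configurable quantile (default 0.25) of the lower component. A unimodal fit
falls back to fixed sample quantiles (0.25, 0.75), flagged, as does EM
failure. The display rescaling is the piecewise-linear map sending
[0, c1] → [0, 1/3], (c1, c2] → (1/3, 2/3], (c2, 1] → (2/3, 1], so the three
statuses occupy equal display thirds and the status boundaries land exactly
on 1/3 and 2/3.

Ranking filters compounds to model AUC > 0.7, requires at least one patient
above probability 0.65 for a compound to enter the cohort report, and orders
each patient's list by probability descending with ties broken by larger
GI50 dynamic range (a wider in vitro response window makes a prediction more
actionable), then compound id — fully deterministic and invariant to input
order.

Coherence: signature genes' co-regulation edges are pairs with
|Pearson r| > 0.5 (default), computed separately in cell lines and tumors;
the Jaccard coefficient of the two edge sets is compared to a null of random
equal-sized gene sets drawn from the shared gene universe,
p = (1 + #null ≥ J) / (1 + n_perm) with n_perm = 9999 by default.

## Association tests and validation harness

Fisher's exact test on 2 × 2 mutation/response tables is two-sided by the
minimum-likelihood convention (sum of hypergeometric probabilities of all
tables with the observed margins no more probable than the observed table);
this is the convention scipy implements and the one the test suite verifies
against exhaustive enumeration. A zero margin returns p = 1 by convention.
Continuous associations use the Welch t test (the safer default when group
variances differ). Survival validation fits Kaplan-Meier curves per
predicted group (lifelines) and reports the two-group log-rank chi-square p;
binary-response validation reports per-class confusion counts at a
probability threshold (ties called resistant) plus the rank AUC.

## Synthetic data generator

The generator defines the study conditions for every benchmark. A panel of
48 lines (the core-set size) draws subtypes at proportions
luminal 0.44 / basal 0.34 / claudin-low 0.13 / normal-like 0.09, with
ERBB2 amplification in 40% of luminal and 26% of basal lines. Continuous
data types (1000 expression, 500 copy-number, 500 methylation features by
default) are unit-variance Gaussian noise plus a 50-feature subtype-marker
block (per-subtype mean shifts of 1.5 SD) — enough structure for subtype to
be learnable from omics — and, in copy number, an ERBB2 locus sitting 2 SD
higher in amplified lines. The 7-gene mutation panel is Bernoulli with
TP53 enriched in basal/claudin-low and PIK3CA in luminal over a 10%
background rate.

Planted compounds define a true sensitivity class (an independent latent
coin for `feature` drivers, subtype membership for `subtype`, an even blend
for `mixed`, ERBB2 status for `erbb2`, none for `null`); true GI50 is a base
of 7.0 −log10(molar) ± half the class separation (default 1.0 log10 unit)
plus N(0, 0.25) noise, and planted features are shifted by the effect size
(default 2 SD) in sensitive lines. Plates invert the dose-response model:
growth is linear in log10(concentration) at 50 %/decade — the slope implied
by a full ~150-point growth transition spanning about three decades — with
its 50% crossing exactly at the true GI50, converted to OD triplicates and
plate backgrounds, optionally with multiplicative OD noise. Noise-free
plates therefore round-trip to the truth up to interpolation error, and
truths placed outside the 1e−9..1e−5 M grid exercise the censoring flags
deterministically. Tumor cohorts reuse the panel's feature space and marker
structure with a known responder fraction carrying the planted shifts.

What the generator does **not** emulate: heavy-tailed and batch-structured
noise, correlated feature blocks beyond the marker sets, probe-level
artifacts, missingness patterns, copy-number segmentation structure, or the
messy relationship between expression platforms. Passing benchmarks
establish that the machinery recovers what was planted under clean
Gaussian conditions; they do not certify performance on real panels.

## Problem sizes of the shipped benchmarks

The test suite and the acceptance script use: 100 random LS-SVM instances
(N ≤ 30) against the dense oracle; exhaustive AUC enumeration for score
vectors up to length 5 over a 3-value alphabet plus 300 random length-8
vectors; 60 random Fisher tables (totals ≤ 100) against exhaustive
enumeration; a 30-line noise-free round-trip panel spanning truths beyond
the tested range; one 48-line recovery panel (15 planted features, 2 SD)
evaluated over 20 splits; 20 null panels at 20 splits each; 20 seeded
replicates for subtype-sufficiency (15 splits per evaluation) and for
mixture-cutoff recovery (n = 300 per replicate). These sizes keep the whole
suite in well under a minute of compute per component while leaving the
statistical margins of the checks intact.

## Known limitations

* Random-forest signatures serialize their metadata but not the fitted
  forest (no text representation); prediction from file is only supported
  for LS-SVM signatures.
* The LS-SVM solve is dense O(N³); fine for cell-line panels (N ≤ 100),
  not intended for large cohorts as training sets.
* Cutoff selection assumes the probability distribution is reasonably
  described by ≤ 3 normal components on [0, 1]; strongly skewed or boundary-
  piled distributions fall back to quantile cutoffs.
* The repeated-measures ANOVA requires complete compound × data-type rows;
  compounds missing any data type are dropped from the overall test (they
  still enter the pairwise tests where observed).
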