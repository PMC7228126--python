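# Methods

## Problem and model

`pseterm` classifies bacterial DNA sequences as transcription
terminators or background. The pipeline is: encode sequences into
numeric features, rank and prune the features, train a classifier,
evaluate by repeated stratified cross-validation. Every stage that
learns anything — position weight models, the min–max scaler, feature
rankings, the incremental-selection prefix, the classifier — is fitted
on training folds only and applied frozen to test folds; this is
asserted structurally in the test suite.

## Feature encoders

**K-pwm.** Site-specific k-tuple probabilities are estimated with
additive smoothing, `p_xi = (n_xi + c)/(N_i + 4^k c)`, where `n_xi`
counts training sequences carrying k-tuple `x` at site `i` and `N_i`
counts training sequences long enough to have site `i` (so mixed-length
training sets need no padding). The per-site weight is the log-odds
against the uniform background `p0 = 1/4^k`, and a sequence's feature
is the mean weight over its scored windows — sequences longer than the
model score their first `n_sites` windows, shorter ones all of their
own. Normalizing by the number of scored windows removes the length
dependence that a summed score would have. Position weight models are
built from the positive sequences of the training fold only, and
rebuilt inside every cross-validation fold: positives-only is the
natural reading of a motif model for the terminator class, and
fold-internal fitting is the leakage-safe choice. Default pseudocount
0.25 per k-tuple per site; with pseudocount 0, never-seen cells are
flagged `-inf` and scoring substitutes a floor weight `ln(10⁻³/p0)`
(configurable) instead of propagating infinities.

**Base content.** The five composition statistics; a ratio with an
empty denominator (e.g. gcSkew of an all-A/T sequence) is reported as 0
and flagged degenerate rather than raising, so batch encoding never
aborts on an extreme sequence.

**Nucleotidepro.** The 47-property positional matrix is flattened
row-major and right zero-padded to a fixed width `L_max` (default 82,
the longest sequence in the curated benchmarks this layout mirrors);
variable-length inputs therefore align by left edge. A dinucleotide
property's last column and a trinucleotide property's last two columns
are structural zeros (no step starts there).

**PseKNC.** K ∈ {4, 5, 6}; defaults λ = 5 correlation tiers and weight
w = 0.1, both exposed in `PseKNCConfig` and recorded in run metadata
(published uses of this encoding rarely state them; these are the
conventional values of its reference implementations). K-tuple
frequencies are counts over the L−K+1 windows divided by L−K+1.
Parallel mode (type I) averages the squared difference of the six
helical step parameters (rise, slide, shift, twist, roll, tilt) between
dinucleotides j steps apart. Series mode (type II) keeps one tier per
property; its per-tier statistic defaults to the squared per-property
difference, which keeps every component nonnegative and makes all
tiers vanish on homopolymers — the properties both modes are tested
against. The alternative product convention
`P_ζ(i)·P_ζ(i+j)` found in some series-correlation formulations is
available via `PseKNCConfig(correlation="product")`; with standardized
property values it can produce negative pseudo-components, which is why
it is not the default. Feature order is lexicographic in A<C<G<T, then
tiers by gap (and property, in series mode).

## Property tables

The three chemical properties (ring structure, hydrogen-bond strength,
functional group; purine/strong/amino = 0) are exact. The packaged 32
dinucleotide and 12 trinucleotide physicochemical tables are
**synthetic stand-ins**: the property *names* follow the field's
standard sets (helical step parameters, duplex thermodynamics,
bendability, nucleosome positioning, ...), but the *values* are
deterministic GC-correlated standard scores, shipped so the pipeline is
self-contained offline. Conclusions about which real physicochemical
property drives terminator recognition must not be drawn from them;
the pipeline's discriminative signal on synthetic data comes from
sequence composition, which any injective property assignment
preserves. Real tables in the same CSV layout (`property,AA,...,TT`)
can be passed to `load_property_table`. Every table is re-standardized
per property at load (mean 0, sd 1 over its k-mers) — a no-op for
files that already hold standard scores.

## Feature selection

F-score uses unbiased per-class variances; a feature with zero
within-class variance but separated class means receives an infinite
sentinel and ranks first, ties break by original column index. The
binomial ranking treats a count feature's `N_j` total occurrences as
draws with class prior `q_i` (the class's sample share) and scores
`CL_j = max_i (1 − P[Binom(N_j, q_i) ≥ n_ij])`, computed with a
numerically stable survival function; it refuses real-valued features
rather than silently binarizing, since the statistic is only defined
for occurrence counts. IFS evaluates every `stride`-th prefix of the
ranking (default stride 32, capped at 256 features) with a small
seeded cross-validation of the downstream model (default 3-fold, 1
repeat), and keeps the smallest prefix attaining the maximum accuracy.
The stride/cap are the package's runtime-accuracy compromise: on the
synthetic benchmark the curve is flat after the first few features, and
both knobs are configurable for exhaustive runs.

## Models, normalization, evaluation

Min–max normalization maps training min/max onto [0, 1] (or [−1, 1]);
constant features map to the range midpoint, and transformed unseen
data is deliberately not clipped. Scaling is applied to margin- and
distance-based learners (SVM, logistic regression, k-NN, MLP, and
ensembles over SVM/logistic bases) and skipped for tree and probability
models, where it is a no-op at best. The zoo's grid-search ranges use
the libsvm-style exponential grid for the SVM, tenth-step learning
rates and 50-step estimator counts (10..960, 20 points) for the
ensembles; grids are searched exhaustively with ties resolved toward
fewer estimators, then smaller learning rate, then declaration order.
A seed listed as a tunable in some published grids is not treated as a
hyperparameter here.

Sn, Sp, Acc and MCC are computed in the complement form
(`Sn = 1 − N+−/N+`, etc.), which the tests verify to agree exactly with
the standard TP/TN/FP/FN definitions on all small confusion tables; an
MCC factor of zero under the root yields MCC = 0. AUC is the trapezoid
area under the ROC curve (equal to the Mann–Whitney statistic under
rank-averaged ties). Cross-validation redraws a stratified 5-fold
partition per repeat; per-repeat metrics are pooled over folds, and the
report carries means and standard errors across repeats. Class
imbalance is handled by stratification only — no resampling. The
prediction threshold is 0.5 on the positive-class probability; an
ROC-optimal threshold is available but off by default.

## Synthetic benchmark

The generator's defaults are the study conditions: 400 positives of
50 bp (9 bp stem with 90% G/C, 5 bp loop, reverse-complement stem,
7 bp poly-T, uniform flanks, random offset) against 400 negatives of
80 bp i.i.d. uniform background. The length asymmetry mirrors curated
terminator benchmarks in which negatives are intercepted from longer
flanking windows. What the simulator does **not** emulate: genomic base
composition and autocorrelation, imperfect stems (bulges, mismatches),
A-tract upstream elements, Rho-dependent terminators, and any homology
structure between sequences — so passing the synthetic recovery test
shows the pipeline can extract a planted hairpin/poly-T signal, not
that it matches published accuracy on real genomes. Because length and
poly-T content alone nearly separate the synthetic classes, recovery
accuracy ≥ 0.95 is expected and observed (~0.998 across seeds).

## Problem sizes and numerical choices

The default evaluation protocol in the tests and the results script
uses 5 repeats of 5-fold CV (the reporting convention scales to 100
repeats via `CVConfig`), IFS as above, and XGBoost with 100 trees —
sizes chosen so a full from-scratch run completes in well under a
minute on one CPU while leaving standard errors small relative to the
effects measured. Stochastic components draw all randomness through
explicit integer seeds (generator, partitions, model); identical seeds
give bitwise-identical datasets, splits and reports.

## Known limitations

Real-data accuracy claims require the curated terminator/non-terminator
tables, which are not distributed here; the replication path
(`cross_validate_pipeline` on a labelled CSV/FASTA) is implemented and
tested only on synthetic data. The binomial ranking is restricted to
count features. The fitted-pipeline file format (joblib, version-tagged)
is stable within minor versions only.
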