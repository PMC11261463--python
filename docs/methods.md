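# Methods

## Scope and data model

The package analyzes cohorts of subjects, each carrying a symmetric
node-by-node FC matrix (unit diagonal, off-diagonal Pearson
correlations), behavioral scores (TEPS subscales and total, HAMD), and
nuisance covariates (age, sex, education, illness duration, framewise
displacement). Edges — unordered node pairs `i < j` — are stored in
row-major upper-triangle order, 0-based; this single convention is
defined in `connectome.py` and used by every module and file format.
Inputs are assumed to be preprocessed regional time series or
precomputed FC matrices; no image-level processing of any kind is
performed.

FC matrices built from time series use plain Pearson correlation.
No Fisher z-transform is applied at any point: the CPM stage consumes
raw r values, and network strength is the sum (not mean, not z-sum) of
the masked edge values. Both choices follow the most common published
CPM workflow; the correlation estimator and strength definition are
deliberately kept in one place each so variants are one-line changes.

## The CPM stage

Cross-validation is leave-one-out by default (k-fold available). Per
fold, the training-set edge-behavior Pearson r and its two-tailed
t-transform p (`t = r√((n−2)/(1−r²))`, `n−2` df) drive selection at
`p < 1e-4` (the default threshold); the positive tail (r > 0) is the
headline network, the negative tail is computed symmetrically, and a
combined positive-minus-negative strength model is available via
`tail="both"`. The linear model is univariate least squares with
intercept.

Implementation note: the per-fold selection statistics are obtained by
leave-one-out downdates of the full-sample cross-products, making one
LOOCV pass O(subjects × edges); the permutation loop reuses every
behavior-independent term. An independently coded brute-force per-fold
loop (explicit `pearsonr` + `polyfit` per fold) is kept in the test
suite and must agree to 1e-10.

Degenerate folds — empty selection, or a strength vector with zero
variance — fall back to an intercept-only model (training-mean
prediction) and are recorded in `CPMResult.empty_mask_folds`. This
keeps LOOCV defined at stringent thresholds. A consequence worth
knowing: under the null, cross-validated predictions are *negatively*
correlated with the observed scores (a training mean without subject s
moves away from `y_s`), so the null distribution of `r_obs` is centered
below zero. This is a known property of cross-validated correlation,
not a bug; the permutation test is calibrated because its null shares
the bias (verified by the type-I-error suite: empirical rejection at
α = 0.05 lies in [0.01, 0.10]).

The permutation test shuffles the behavior vector across subjects (FC
fixed), re-runs the full cross-validated procedure, and uses the
add-one estimator `p = (1 + #{r_null ≥ r_obs})/(1 + N)`, ties counting
as exceedances, so p is never zero and is valid for any N. Iteration
`i` draws its permutation from `default_rng([seed, i])` — a
deterministic substream per iteration, reproducible under any execution
order or parallelization.

The consensus network is the across-fold intersection of the selected
masks (union and fraction-threshold aggregation would be
straightforward alternatives; intersection is the most conservative
reading of a single reported network and is what the hub criterion is
applied to). Hubs are nodes with ≥ 5 incident consensus edges; degree
records are sorted by degree descending, ties by node index. Lobe- and
gyrus-level summaries count mask edges per unordered region pair, so
the upper triangle (diagonal included) of the summary matrix sums to
the mask's edge count.

## Group statistics

The seed-FC comparison extracts, for each hub seed and every other
node, the per-subject FC value and applies a pooled-variance
independent-samples t-test between the two patient groups (Welch by
flag). Bonferroni correction defaults to m = the number of tests
actually performed in the call, and m is always recorded in the output,
since a reported corrected p is uninterpretable without its family
size. Partial correlation residualizes both variables on the covariates
plus intercept by least squares and correlates the residuals, with
`df = n − 2 − k`; the classical second-order recursion formula and
pingouin serve as independent oracles in the tests. The
summary-statistic forms (one-way ANOVA from mean/SD/n, pooled t from
summaries, chi-square from a contingency table) exist so published
demographic tables can be checked without raw data; ANOVA from exact
summaries is verified to equal a raw-data ANOVA.

## SVM classification

The LIBSVM-style workflow: per training fold, features are affinely
mapped so the training min/max land on −1/+1 (held-out values may fall
outside, by design); `c` and `g` are grid-searched over powers of two
(`2⁻⁵…2¹⁵` and `2⁻¹⁵…2³` by default) on seeded stratified five-fold
CV; the winning pair (ties to smallest c, then g) is reported with the
pooled confusion matrix over its test folds, so each subject is counted
exactly once. Standard errors are the across-fold SD of each metric
divided by √k, with folds lacking the relevant class excluded from
that metric. Selection is non-nested — the grid is chosen on the same
CV whose metrics are reported, mirroring the emulated workflow — which
optimistically biases the reported accuracy; nested CV is the unbiased
alternative and the null-calibration test quantifies the bias (mean
selected accuracy on label-shuffled data stays within 0.08 of the
majority-class rate). The quadratic-programming solver is
scikit-learn's SVC; this package owns scaling, folding, selection, and
metrics.

## The synthetic cohort generator

The generator's defaults are the emulated study's design: groups of
31/28/32 (melancholic, non-melancholic, control), 246 nodes, behavior
and covariate means/SDs per group from the study's demographic table,
male/female counts likewise, and 26 planted positive edges split
between two hub nodes — 9 on a right inferior-temporal analog, 7 on a
right parahippocampal analog (degrees mirroring the reported
highest-degree nodes), the remaining 10 scattered — with the
subtype-difference edge joining the parahippocampal hub to a left
cingulate analog, melancholic patients lower.

FC is generated at the edge level:

```
edge = base + β·z(behavior) + ε,   β = σ·r/√(1−r²),   ε ~ N(0, σ²)
```

with behavior z-scored over patients, `σ = noise_sd = 0.2`, planted
base 0.3, non-planted base 0.1, and values clipped to (−0.999, 0.999).
This gives each planted edge an edge-behavior correlation of `r`
(default 0.5) in expectation. The subtype shift is `±d·σ/2` per group
on the designated edge; d is expressed in residual-noise units, so the
realized standardized difference on a behavior-planted edge is slightly
smaller than d (the behavior term adds variance) plus a small
contribution from the groups' behavior-mean difference. Scores are
truncated Gaussians within each scale's valid range. Baseline FC level
and noise scale were fixed once at values typical of resting-state
edge distributions (off-diagonal r centered near 0.1 with SD ≈ 0.2).

An optional time-series mode draws node signals from the nearest-PSD
completion (eigenvalue clipping, diagonal rescaling) of each subject's
target correlation matrix, so that empirical Pearson FC approximately
realizes the planted values; 200 time points by default.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: subject FC matrices in edge mode are not
constrained positive definite (the analyses consume edge values only);
edges are independent given behavior (no spatial autocorrelation or
network-block structure); behavioral scales are drawn independently of
one another, so cross-scale correlations (e.g. a subscale with its
total) are absent, which makes partial correlations against non-target
scores weaker than in real cohorts; and there is no head motion,
scanner noise, or site structure. The near-perfect synthetic
`r_obs` (~0.9) reflects 26 clean planted edges, not expected real-data
performance.

## Problem sizes and numerical choices

Validation runs use reduced but structurally faithful sizes chosen to
keep the full suite in a few minutes: permutation-calibration replicates
at 30 subjects × 100 edges × 200 permutations × 100 cohorts; parameter
recovery at the full design (59 patients, 246 nodes) over 20 seeds with
planted r = 0.6; seed-FC power at d = 1.5 over 50 cohorts and
family-wise error at the null over 200 cohorts; the acceptance script
runs the full pipeline with 200 permutations. Tolerances: oracle
equivalences at 1e-10–1e-12 (pure floating-point agreement); published
summary statistics at 2% relative (the printed inputs are rounded);
simulation-based rates at the bands stated in each test. Symmetry
tolerance for FC validation is 1e-10, with the diagonal forced to
exactly 1 after computation. The reported sensitivity for the published
29/31 count is 93.548…%, which rounds to 93.55; the emulated report
printed 93.54 (truncation), so the worked-example check is asserted at
±0.01, the printed precision.

## Pipeline

`run_pipeline` wires the stages in dependency order — simulate (or
load) → CPM → hub-seeded group comparison (falling back to the two
highest-degree nodes when no node reaches the hub threshold) → partial
correlation and classification on the comparison's top edge (both
overridable) — and writes `manifest.json` with config, per-stage seeds
(derived from the master seed via `default_rng([seed, stage_index])`),
package version, and output inventory. Re-running a configuration
reproduces every output byte-identically. All outputs are TSV/JSON.
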