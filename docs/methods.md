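# Methods

## Forest engine

Forests are scikit-learn `RandomForestClassifier`/`Regressor` ensembles
(Gini splits for classification, variance reduction for regression;
bootstrap samples of size n drawn with replacement — the classical
choice). Defaults follow the benchmark parameterization: `ntree = 10000`,
`mtry = round(0.33 p)` candidate variables per split, terminal nodes of
at least `round(0.10 n)` individuals. Boruta instead uses its reference
defaults, `mtry = floor(sqrt(p))` and nodesize 1 (classification) / 5
(regression). Fractions resolve against the training matrix actually
used (so the hold-out variant resolves nodesize against a half sample,
and RFE re-resolves mtry as variables are removed).

Per-tree bootstrap membership is reconstructed from each tree's integer
random state, which reproduces sklearn's bootstrap draw exactly; a test
verifies that the resulting OOB error equals sklearn's own `oob_score_`.

**Permutation importance** is the raw (unscaled) mean performance drop:
for each tree, performance on its evaluation rows is compared before and
after shuffling one variable's values, and differences are averaged over
trees (trees that never split on the variable contribute exactly zero;
trees without evaluation rows are skipped). Performance is accuracy for
classification and negative mean squared error for regression, so
relevant variables score positive in both tasks. The Z-score-scaled
variant is deliberately not offered: its null distribution is not
normal, which would invalidate the parametric p-values of the Altmann
procedure. One fresh shuffle is drawn per tree and variable; all streams
derive deterministically from a single seed, so a fixed seed gives a
bit-identical importance vector.

Two evaluation-row choices give the two importance flavours:

* **OOB importance** evaluates each tree on the rows absent from its
  bootstrap sample. Its null distribution is positively skewed.
* **Hold-out importance** splits the data once into two equal halves
  (stratified by class for classification), trains a forest on each
  half, scores it by permutation importance on the *other* half, and
  averages the two per-variable scores. Its null distribution is
  centred at zero with balanced tails, which is the property Vita's
  mirrored-null construction exploits. A single half-split is used per
  call — the procedure is defined by exactly two forests, not by
  repeated splitting.

  A subtlety worth knowing: the *sample skewness* of the hold-out null
  over thousands of variables is a heavy-tailed, unstable statistic at
  n = 100. Its sign and magnitude move systematically with tree depth
  and mtry (deep trees pull it negative, the benchmark's 10%-nodesize
  shallow trees push it to +3 and beyond), and the reference
  implementation behaves the same way on matched data. The reliable
  contrast with the OOB null is the location of the positive mass: OOB
  null importances carry a strongly positive outlier tail at every
  parameterization tried, while hold-out null scores stay mean-zero
  with roughly half of the used variables scoring negative.

## Selection procedures

All thresholds below are the benchmark's defaults (Boruta confidence
0.01; Perm 500 permutations, p-threshold 0; Altmann 50 permutations,
p-threshold 0; r2VIM 20 runs, factor 3; RFE removal fraction 0.1,
tolerance 10%; Vita p-threshold 0).

**Boruta.** Each run appends one shadow copy per undecided variable
(values freshly permuted across rows), fits a forest, and counts a *hit*
for a variable whose importance strictly exceeds the best shadow
importance. After every run, one-sided binomial tails of the hit count
against Binomial(runs, 1/2), Bonferroni-corrected across the undecided
variables of that round, confirm or reject variables at the configured
level. Rejected variables and all shadows are removed and the loop
repeats until everything is classified or `max_runs` (default 100, the
reference implementation's default) is reached; leftovers are reported
as *tentative* and are not counted as selected. Shadows are built only
for undecided variables; confirmed variables remain in the design matrix
but are no longer tested.

**Vita.** Hold-out importance is computed once; the empirical null is
the multiset of non-positive scores together with their mirror images
around zero, and each variable's p-value is the fraction of null values
greater than or equal to its score (weak inequality, so p = 0 means
strictly above every null value — attainable because p-values are r/N,
not (r+1)/(N+1)). If no score is non-positive the data are not in the
high-dimensional regime the estimator assumes and an error says so.

**r2VIM.** `n_runs` forests differ only in seed; each run's importances
are divided by the absolute value of the run's minimal importance (a
run whose minimum is exactly zero falls back to the minimum over all
runs; if every run's minimum is zero the null scale is undefined and an
error is raised). A variable is selected when its *minimum* relative
importance over runs is greater than or equal to the factor.

**Perm / Altmann.** The outcome is permuted `n_permutations` times, a
fresh forest is trained per permutation, and each variable accumulates
its own null sample of importances (per-variable nulls, the natural
generalization of the parametric variant; the two procedures share the
same permutation forests when run together). Perm uses the empirical
tail fraction as p-value; Altmann fits a normal distribution per
variable by maximum likelihood (mean = sample mean, sd with N
denominator) and takes the upper-tail probability. At the default
p-threshold 0, Altmann selection requires the tail probability to
underflow to exactly zero in double precision (z ≳ 39) — intentional, as
the default is only meant to fire for unambiguous signal. A
zero-variance null degenerates to p = 0 above the null mean and 1
otherwise.

**RFE.** Fit, record OOB error, drop the `floor(0.1 p)` (at least one)
least important variables with importance recomputed at every step,
down to a single variable. With e* the minimal OOB error over steps, the
smallest variable set whose error is at most e*(1 + tol/100) is
returned — smallest because the method's goal is a minimal set.

Empty selections are legal; downstream evaluation defines the FDR of an
empty selection as 0 and falls back to the trivial predictor for its
prediction error.

## Simulation designs

**Correlated groups (regression).** Six latent base variables
x1..x6 ~ U(0,1) each spawn a group of `group_size` noisy copies
v_ij = x_i + c_j·N(0, 0.3) with c_j = 0.01 + 0.5(j−1)/(group_size−1), so
within-group correlation with the base decays from ≈0.99995 (c=0.01) to
≈0.884 (c=0.51). The outcome is

    y = 0.25·exp(4x1) + 4/(1 + exp(−20(x2 − 0.5))) + 3·x3 + ε,  ε ~ N(0, 0.2),

so groups 1–3 are causal (with decreasing effect), groups 4–6 are
correlated decoys, and the remaining predictors are i.i.d. U(0,1) noise.
The base variables themselves are not predictors. In the null variant
the outcome is the sum of three independent N(0, 0.2) draws — any
outcome independent of the predictors preserves the null, and the
additive combination is the simplest; the noise parameter is read as a
standard deviation. Replicates are generated from per-replicate child
seeds of one master seed.

**Multivariate-normal classification.** Predictors are zero-mean MVN
draws with a supplied covariance; 25 variables per effect size in
{−3, −2, −1, −0.5, 0.5, 1, 2, 3} (200 causal in total) are chosen
uniformly at random, and a seeded random half of the 200 individuals
forms class 1, whose causal means are shifted by the effect size.
Replicates come in pairs sharing causal variables and effect sizes. In
the original study the covariance was estimated from a breast-cancer
expression data set; obtaining that estimate requires external data, so
the package substitutes a synthetic block-exchangeable covariance
(`standin_covariance`: unit variances, constant within-block
correlation, PSD by construction) while also accepting any user-supplied
matrix.

What the generators deliberately do not emulate: real omics correlation
structure is neither block-exchangeable nor group-wise decaying,
effect mechanisms are not mean shifts only, and measurement noise is not
homoscedastic. Passing benchmarks on these designs shows the selectors
behave as specified under known ground truth, not that their power
estimates transfer to any particular experimental platform.

## Desk-scale study conditions

The reference experiments are cluster-scale (5000 predictors, 10 000
trees, 500 permutations, 50+50 replicates, ~16 CPUs). The canned studies
in `rfvarsel.study` reproduce the two effect scenarios and the null
model at sizes a single CPU completes in minutes, chosen from fit-time
measurements before any benchmark numbers were inspected:

* group-size 50: 450 predictors (300 group + 150 noise), 100
  individuals, 10 replicates;
* group-size 10 and the null model: 250 predictors (60 group + 190
  noise), 100 individuals, 10 replicates;
* trees per forest by method — Vita 1000, Boruta 500 (group size 50) /
  400 (group size 10), Perm and Altmann 300, r2VIM and RFE 250 —
  reflecting how many forests each method trains per replicate (2, ≤80,
  51, 20, ~45 respectively); Boruta's run cap is 80 at desk scale
  (beyond that only one or two tentative stragglers remain in play);
* Perm reduced to 50 outcome permutations, shared with Altmann, and run
  on the first 4 of the 10 replicates — these two methods train an
  order of magnitude more forests than the rest, and the original
  comparison likewise ran Perm on only 40% of its replicates.

Consequences of the scaling, observed and accepted rather than tuned
away: with fewer noise variables the empirical null maxima are lower,
which pushes Vita's and Perm's selections slightly up; r2VIM's false
positives (a count proportional to the noise-variable pool) all but
vanish, so its desk-scale FDR sits at 0 rather than the full-scale
≈0.09; and RFE's error-tolerance rule picks smaller sets than at full
scale, lowering its sensitivity in the group-size-10 scenario. The
acceptance tests state the full-scale medians with Monte-Carlo
tolerances; where a desk-scale artifact moves a quantity outside the
band, the test is left failing rather than widened.

## Numerical choices and edge cases

* Empirical p-values use r/N so the p = 0 thresholds are attainable.
* Bonferroni (not FDR) correction inside Boruta, matching the reference
  implementation; ties in importance sorts are broken by original
  column order (stable sorts throughout).
* Quartile binning uses linear-interpolation quantiles with lower-closed
  bins; constant vectors bin to 1 with a warning. Standardization uses
  the population (N) standard deviation, consistent with the Altmann
  MLE convention.
* Benchmark orchestration seeds each replicate from a CRC of its data
  matrix combined with the master seed, making aggregate results
  invariant to replicate ordering; all derived seeds stay below 2^31.
* Stability of two empty selections is defined as 1; the Jaccard
  denominator of the modified index is the smaller set size.

## Known limitations

Binary outcomes only (no multiclass or survival forests); no missing
values; no Gini importance (biased for correlated/many-valued
predictors); Vita and r2VIM require genuinely high-dimensional inputs
with many uninformative variables; Boruta's run-time grows with the
number of undecided variables and can hit `max_runs` with tentative
variables, which are reported but never counted as selected.
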