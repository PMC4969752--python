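# Methods

This note documents the statistical models and algorithms implemented in
`vivoplan`, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## The design problem

Preclinical intervention studies allocate a pool of N animals (or tumors)
to G intervention arms and follow a longitudinal response such as serum
PSA in a xenograft model. Baseline characteristics — body weight, baseline
response level, batch, litter — both confound and predict the response.
`vivoplan` treats allocation as an optimization problem followed by a
randomization step, and then reuses the resulting matching structure in
the post-intervention analysis.

## Dissimilarity

Baseline similarity between units i and j is summarized in a symmetric,
zero-diagonal N x N matrix D. Numeric covariates enter through one of
five metrics (`euclidean`, `manhattan`, `standardized-euclidean`,
`mahalanobis`, `gower`), with optional nonnegative per-covariate weights
multiplying each covariate's contribution before aggregation.

- The default is **standardized-euclidean** (z-score each column, then
  Euclidean). Baseline covariates come in incommensurate units (grams,
  ug/l, fold changes); standardization makes the metric scale-free without
  requiring the covariance estimate that Mahalanobis needs.
- **Gower** is the range-normalized mean absolute difference; zero-range
  columns contribute 0 with a warning.
- **Mahalanobis** refuses (near-)singular covariance with a pointer to the
  standardized metric rather than silently regularizing.

Categorical covariates are handled in one of two modes:

- **strict** — a label mismatch sets D[i, j] = +inf. Units from different
  strata can never share a submatch, which forces every arm to receive an
  equal share of each stratum.
- **relaxed** — each mismatching categorical covariate adds a penalty
  (default 1.0, times the covariate's weight) to D[i, j]. The default of
  1.0 is deliberately on the scale of the default standardized metric:
  one categorical mismatch costs about as much as a one-SD difference in a
  numeric covariate. With penalty 0 the categorical columns are ignored;
  as the penalty grows, relaxed solutions converge to the strict ones
  (property-tested on small instances).

Missing covariate values are a hard error at distance-computation time.
Imputation would silently distort the distances that drive the whole
design, so the user must either drop the unit or the covariate.

## Optimal multigroup non-bipartite matching

A *submatch* is a set of G mutually matched units; a feasible solution
partitions all N units into K = N/G disjoint submatches. Equivalently the
solution is a binary symmetric zero-diagonal matrix X with all row and
column sums G-1 in which each connected component is a G-clique. The
objective is the sum over submatches of all within-submatch pairwise
distances, i.e. (1/2) * sum(X * D), minimized over feasible X. For G = 2
this is weighted non-bipartite perfect matching; for G > 2 it is an
NP-hard set-partitioning problem, which is why three solvers ship:

**Branch and bound (`solve_exact`).** Submatches are built sequentially.
Each new submatch is anchored on the lowest-indexed unassigned unit, which
eliminates all symmetric re-orderings of the same partition from the
search tree; its completions (the (G-1)-subsets of the remaining units)
are expanded best-first by incremental clique cost. The lower bound for a
partial solution is the accumulated cost plus, for every unassigned unit,
the sum of its G-1 smallest finite distances to other unassigned units,
divided by two (each within-submatch edge is incident to two units). The
bound is admissible: any completion gives each unassigned unit exactly
G-1 incident edges among the currently unassigned units, each counted
twice. Since children are cost-ordered, a child exceeding the incumbent
prunes all its later siblings. A greedy pass (grow each submatch from the
lowest free unit by cheapest insertion) supplies the initial incumbent.
Infinite entries make a clique inadmissible and are excluded from bounds,
so strict-mode constraints prune early; if no finite-cost partition
exists the solver reports infeasibility rather than a best effort. Among
equal-cost optima the lexicographically smallest canonical representation
(submatches sorted, ordered by smallest member) is returned, making
results bit-for-bit reproducible. An optional wall-clock limit returns
the best incumbent with `optimal=False`.

The practical range of the exact solver is roughly `count_partitions(N, G)`
up to a few hundred million with informative distances; the automatic
solver choice in `match_by_batch` switches to the GA above 2 x 10^6 raw
partitions, a deliberately conservative threshold.

**Genetic algorithm (`solve_ga`).** Chromosomes are permutations of the N
unit indices, decoded by chunking consecutive blocks of G — every
individual is feasible by construction. Operators: tournament selection
(size 2), order crossover (rate 0.9), per-position pairwise swap mutation
(rate 0.05), elitism of one. Defaults: population 100, at most 500
generations, early stop after 100 stagnant generations. All randomness
flows from one seed, so runs are reproducible; the result is labeled
`optimal=False` and upper-bounds the exact optimum (property-tested).

**Brute force (`brute_force`).** Anchored exhaustive enumeration with a
guard at 10^7 partitions. It exists as the independent oracle for the
other two solvers and is used only in tests and the acceptance script.

**Batch stratification.** With a batch column, each batch is solved as an
independent matching problem and the partitions are concatenated. No
submatch spans batches, so after randomization every batch is spread
exactly evenly over arms — batch effects cannot correlate with treatment.
Each batch size must be divisible by G.

## Randomization, blinding, balance diagnostics

`randomize_within_submatches` draws an independent uniform permutation of
the arm labels inside every submatch; no arm, including the control, is
treated specially. Blinded codes `T1..TG` are mapped to arms by a separate
random permutation so the codes carry no arm semantics; the key is written
to its own file and never printed.

`simulate_balance` replays `n_sim` allocations — fully random, or fresh
within-submatch randomizations over one fixed optimal partition — and
tests every covariate across arms per replicate (one-way ANOVA for
numeric, chi-square of arm x category counts for categorical covariates,
the latter because the F test has no natural categorical analogue). It
reports per-covariate and any-covariate imbalance frequencies at level
alpha. The matched mode deliberately reuses a single partition and only
re-randomizes labels: that is what "matched randomization" means
operationally, since in practice the optimizer output is fixed before the
(repeatable) randomization step. ANOVA p-values are computed vectorized
across replicates from the sum-of-squares decomposition, with degenerate
zero-variance cases mapped to p = 1.

## Mixed-effects models

**Unmatched.** y_{i,t} = b0 + b1 x_t + b2 g2_i x_t + g_{i,0} + g_{i,1} x_t
+ e_{i,t}, with g2_i the indicator of the tested arm: b2 is the
arm-by-time interaction, i.e. the growth-slope difference attributable to
the intervention. Unit-level random intercept and slope are independent
Gaussians by default (that is the structure displayed by the generating
model), with `correlated=True` switching to an unstructured 2 x 2
covariance for users who want the lme4-style default.

**Matched.** Within each submatch, the member of the tested arm is paired
with the member of the reference arm and their responses are differenced
at shared time points only. Delta is modeled as
b_intervention * x_t + g_0 + g_1 x_t + eps with pair-level random effects.
The fixed intercept and common slope are pinned at zero by default:
pairing baseline-similar units makes them redundant, and omitting them
concentrates the information in the single intervention term.
`free_intercept_slope=True` frees the intercept (a diagnostic for residual
baseline mismatch); a freed common slope would be exactly collinear with
the intervention slope in a single contrast and stays at zero. The sign
convention is treatment minus reference, so a negative effect means slower
growth under treatment. For G > 2, pairs are formed per tested contrast
(each arm's submatch member against the reference arm's member; any two
arms can likewise be contrasted directly).

Differencing at shared time points has a deliberate consequence under
right-censoring: when either member of a pair drops out, the pair's later
time points vanish for *both* members, so censoring never enters the
analysis one-sidedly.

**Estimation and inference.** Fitting goes through statsmodels' `MixedLM`
(REML by default, L-BFGS with a Powell fallback; convergence is reported,
never silently patched). P-values for fixed effects use Satterthwaite's
approximation: df = 2 g^2 / Var(g) with g(theta) = Var(c'beta_hat) =
[c' (sum_i X_i' V_i^{-1} X_i)^{-1} c], differentiated by central finite
differences over the variance parameters theta, and Var(theta_hat) taken
from the finite-difference Hessian of the profiled REML criterion
(implemented here because no installed Python package provides
Satterthwaite df). In the balanced one-way random-intercept design this
machinery reproduces the closed-form df = clusters - 1 to five decimals,
and on a shared fixture it agrees with lmerTest's implementation to four
decimals in df (cross-checked in the test suite via Rscript). When the
curvature is unavailable (variance estimates on the boundary, indefinite
Hessian) the residual df is used and a warning is recorded in the fit; a
normal-approximation p-value is always reported alongside for
transparency. Noise-free data (zero residual variance) short-circuit to
the exact OLS solution rather than fighting a degenerate likelihood.

**Paired Hotelling T^2.** For single end-point (possibly multivariate)
comparisons, the within-submatch pairing feeds a one-sample T^2 test of
the paired difference vectors against zero, with the exact
F_{d, n-d} reference distribution. At d = 1 it reduces to the squared
paired t statistic (asserted exactly). Singular difference covariance is
an error suggesting endpoint reduction, not a pseudo-inverse.

## Bootstrap power

Power is estimated by resampling the *data*, not by simulating from fitted
parameters: whole sampling units are drawn with replacement from the
source dataset — individual animals (within arm) for the unmatched model,
matched pairs for the paired model — so trajectory lengths, censoring
patterns and within-unit correlation are preserved exactly in every
resample. At each candidate per-arm size n, `n_boot` resampled datasets
are refit and power is the fraction with the intervention term's p below
alpha. Refits that fail are dropped but remain in the denominator
(conservative); grid points with more than 10% drops are flagged.
Per-replicate RNG substreams are derived from (seed, grid index,
replicate), so results are independent of execution order. `required_n`
is the smallest grid n with power at or above the target (default 0.8,
the conventional design threshold). Monte-Carlo uncertainty is reported
as sqrt(p(1-p)/n_boot) per grid point.

Defaults (grid 3..40, n_boot 1000) are this package's own choices; the
worked examples and the acceptance script use coarser grids and
n_boot 200-500, which resolve power to a Monte-Carlo SE of about 1.5-3
percentage points — adequate for locating the 0.8 crossing on a grid.

## Synthetic data

`synthdata` generates studies with exactly the structure the models
assume: linear growth with unit-level Gaussian random intercepts/slopes,
arm-specific slope offsets, i.i.d. Gaussian noise, and optional
right-censoring whose per-time hazard scales with exp(coef * standardized
latent slope), emulating the ethical-endpoint censoring of aggressive
growers. Default population values (intercept 14, slope 10 per week,
random-effect SDs 8 and 5, residual SD 6, N = 45, G = 3) are of the
magnitude of a castration-resistant VCaP PSA study, so tests run under
realistic signal-to-noise ratios. Informative covariates are constructed
as rho * z_slope + sqrt(1 - rho^2) * noise (default rho 0.8) and then
shifted to plausible measurement scales — the simplest mechanism that
makes a covariate "prognostic" — with the hidden random effects returned
separately so tests can score against the truth.

What the generator does **not** emulate: nonlinear (e.g. Gompertz or
nadir-then-regrowth) response shapes, non-Gaussian noise, lower detection
limits, litter/cage hierarchies beyond a single batch factor, and
covariates that are prognostic through anything other than the random
slope. Passing tests therefore certify the pipeline under its own model
assumptions; they do not certify robustness to model misspecification.

## Numerical choices and degenerate inputs

- Cost comparisons in the solvers use an absolute tolerance of 1e-9;
  cost ties are broken lexicographically.
- Dissimilarity validation flags asymmetry/diagonal/negativity beyond
  1e-10.
- ANOVA and the matched fit return p = 1 (with a warning or note) for
  exactly degenerate inputs (zero variance, all-zero differences) instead
  of NaNs.
- N not divisible by G — overall or within a batch — is a hard error;
  phantom/padding units are out of scope.
- Finite-difference steps for the Satterthwaite machinery are
  max(1e-5, 1e-3 |theta|) for the Hessian and max(1e-6, 1e-4 |theta|) for
  the gradient; estimated df is clipped to [1, residual df].

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data:
exact-vs-oracle comparisons at N up to 9 (100 instances per shape in the
tests, 60 in the script), balance simulations at N = 45 with 10,000
replicates, model calibration with 600-1,000 simulated fits at 15 pairs,
recovery at 200 units or pairs per arm over 40-50 seeds, and power curves
at n_boot 200-500 — sizes chosen so each property is resolved with
Monte-Carlo error well inside its assertion band.

## Known limitations

- Exact matching beyond a few tens of units (or G >= 5 at N >= 20) falls
  back to the GA; the GA carries no optimality certificate.
- Satterthwaite df can fall back to residual df at boundary variance
  estimates; the fallback is recorded in the fit's notes.
- The paired analysis requires both pair members observed at a time point;
  heavy asymmetric censoring shortens pairwise trajectories and costs
  power (this is the price of the pairing's built-in censoring symmetry).
- Dynamic/longitudinal re-allocation and covariate-adaptive minimization
  are out of scope, as are analytical power formulas.
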