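# Methods

## Model and problem setting

A cohort of *n* subjects carries a binary outcome `Y ∈ {0, 1}`, fully
observed, and *p* predictors `X = (X_obs, X_mis)` with arbitrary missing
cells.  The substantive model is plain logistic regression,
`logit P(Y=1 | x) = β₀ + xᵀβ`, fitted without variable selection.  The
quantity of interest is the out-of-sample predicted probability for each
subject, and the question is how that probability should be constructed —
and honestly assessed — when multiple imputation is used for the missing
predictors.

Two estimation targets must be distinguished.  For *effect estimation* it
suffices to average over the missing data: draw imputations
`X̂_mis,k ~ p(X_mis | X_obs, Y)`, estimate the coefficient mode `β̂ₖ` on each
completed dataset and pool with Rubin's rules, `β̂_MI = (1/K) Σₖ β̂ₖ`.  For
*prediction* the relevant integral also runs over the coefficients: the
predictive density averages `P̂ₖ = E(Y | β̂ₖ, X̂_mis,k, X_obs, Y)` over the
joint uncertainty in `(β, X_mis)`, giving `P̂_MI = (1/K) Σₖ P̂ₖ`.  Prediction
averaging targets this second integral; coefficient pooling targets the
first and then plugs the pooled mode into the model.  The package
implements both (plus the mean-imputed-predictor variant of pooling) so
their behaviour can be compared like for like.

## Outcome masking in cross-validation

Within L-fold cross-validation, each fold in turn plays the role of future
data.  Its outcomes are marked missing *before* imputation; the
chained-equations cycle then treats the masked outcome as one more
incomplete (binary) column, so imputation models still condition on the
outcome wherever it is legitimately available, while validation outcomes
cannot reach the imputation of validation predictors.  The imputed outcome
values are discarded once the fold's predictors are completed.  The
prediction model itself is fitted only on calibration rows, with their true
outcomes.  This yields the exact leakage guarantee checked in the test
suite: arbitrarily altering a fold's outcomes before masking leaves that
fold's predictions bit-identical under a fixed seed.

Fold partitions are uniformly random, unstratified, with sizes differing by
at most one.  L = 10 throughout by default.

## The three calibration strategies

* **Approach 1 (prediction averaging).**  K repetitions; each draws a fresh
  fold partition, generates a *single* imputation per fold on the
  outcome-masked data, fits one logistic model per fold, and predicts.  The
  K probabilities per subject are pooled by their mean (median available).
  K distinct models predict each subject.
* **Approach 2 (Rubin pooling).**  One fold partition, fixed across
  imputations.  Per fold: K imputations, K fits, one pooled coefficient
  vector, applied to each of the K imputed validation predictor sets.  The
  K predictions coincide for subjects with no missing predictors.
* **Approach 3.**  Approach 2's pooled model applied once per subject to
  predictors whose missing cells are replaced by the per-cell mean over the
  K draws (continuous and 0/1 binary cells: arithmetic mean entering the
  linear predictor directly; categorical cells: modal level, ties broken
  toward the first level in the declared order).

Probabilities are pooled on the probability scale (the mean matches the
predictive-density approximation exactly; logit-scale pooling was
deliberately not used).  All three approaches coincide exactly at K = 1
under a shared seed, which the random-number layout guarantees by
construction (see below).

## Chained-equations imputation engine

One draw = a random starting fill (each missing cell replaced by a uniform
draw from its column's observed values) followed by `n_cycles` sweeps over
the incomplete columns, visited in ascending order of missing count (ties
by column position, the outcome last).  Per target column:

* **continuous** — normal linear regression of the target on all other
  predictors plus the outcome; residual variance drawn from a scaled
  inverse-χ² (RSS / χ²_{n_obs − q}), coefficients from
  N(β̂, σ²(XᵀX + ridge·I)⁻¹); then type-1 predictive mean matching: observed
  rows ranked by |predicted mean under β̂ − missing row's predicted mean
  under β*|, one of the `pmm_donors` closest donated uniformly at random
  (boundary ties resolved by a random permutation of the donor order).
  Imputed values are therefore always members of the column's observed
  value set.
* **binary** — logistic MLE, coefficient draw from the asymptotic normal,
  Bernoulli imputation.
* **categorical** — the multinomial analogue via statsmodels' MNLogit, with
  an observed-frequency fallback draw (plus warning) if the multinomial fit
  fails.

Defaults: `n_cycles = 5`, `pmm_donors = 5`, `ridge = 1e-5`, matching common
chained-equations practice; all configurable.

## Logistic fitting and degenerate cases

Fitting is by iteratively reweighted least squares with step-halving.
Convergence: max |score| < 1e-8 or relative deviance change < 1e-10, at
most 100 iterations.  A singular design, non-convergence, or fitted logits
beyond ±20 (an unbounded likelihood in practice) trigger a ridge-penalized
refit on the slopes — `1e-6·n` for analysis models — with a warning.  For
*binary imputation* models the fallback penalty is `max(ridge, 0.1)`: under
complete separation a near-zero penalty leaves the asymptotic covariance so
diffuse that the coefficient draw destroys the signal, and imputations of a
perfectly predictive column would be close to coin flips; a penalty of 0.1
keeps the draw concentrated while still finite.  Predicted probabilities
are clipped into the open interval by 1e-12.

Rubin pooling is the exact arithmetic mean of the per-imputation
coefficient vectors; within- and between-imputation variance components are
recorded for reporting only.  Where all K values being averaged are
identical (pooled coefficients of identical fits, pooled predictions of
complete records, averaged imputations of observed cells) the mean is
short-circuited to that value, because floating-point `K·a/K` can drift by
one ulp and the package promises bit-exact reductions (complete data ≡
plain cross-validated logistic regression).

## Evaluation measures

Per replicate analysis r: Brier score `B_r = (1/n) Σᵢ (P̂ᵢᵣ − Yᵢ)²`,
averaged over replicates.  Imputation variation: per subject, deviations
`Dᵢᵣ = P̂ᵢᵣ − P̄ᵢ` of replicate predictions from the subject's replicate
mean; subjects with `P̄ᵢ < 0.2` or `P̄ᵢ > 0.8` are discarded (between-
replicate spread of a probability is approximately homoscedastic inside
that band; the bounds themselves are retained), and
`R = (Q₀.₉ − Q₀.₁) × 100` of the surviving pooled deviations.  Quantiles
use linear interpolation between order statistics (the "type 7"
convention) — stated explicitly because R's absolute value depends on the
convention at small n.  Bias (simulation only): `(1/n) Σᵢ (P̂ᵢᵣ − Pᵢ)`
against the true probabilities, averaged over replicates.

Every measure is reported on three partitions — all rows, fully observed
records, partially observed records — with record status taken from the
*original* missingness mask, never from imputed data, and models always
calibrated on the full data (this is not complete-case analysis).  An
empty or fully filtered partition yields an explicit null, never a silent
zero.

## Simulation design

Predictors `X ~ N₄(0, Σ)`; outcome `Y ~ Bernoulli(expit(β₀ + Xβ))`.
The scenario grid is a 2³ design: `β₀ ∈ {−1.39, 0.405}` (baseline event
rate 0.2 or 0.6), `β₁ ∈ {log 1.1, log 2}` (weak or strong effect of the
incomplete predictor), missing rate in `{10%, 50%}`, coded L/H per axis
("LLL" … "HHH"); `β₂ = log 2`, `β₃ = log 0.85`, `β₄ = log 0.75` fixed.

Σ defaults to a fixed, documented SPD matrix with standard deviations
(1.0, 1.5, 0.8, 1.2) and correlations between 0.15 and 0.40 — a synthetic
stand-in with the heterogeneous-variance, moderately-correlated character
of real clinical covariates; any user-supplied SPD matrix is accepted.
Because Σ is a package choice, the simulation's value lies in qualitative
comparisons (approach 1 vs 2, K small vs large, weak vs strong effect),
not in matching any particular published table.

Missingness is introduced in x1 only.  MCAR: independent masking at the
target rate.  MAR: row i masked with probability
`Uᵢ = min(x2*ᵢ · M / mean(x2*), 1)` where `x2*` is min-max scaled within
the dataset (so the mechanism is sample-dependent by design, and the row
attaining min(x2) is never masked).  The constant M is calibrated per
dataset: in the untruncated regime `mean(U) = M` exactly, so M equals the
target rate; otherwise M is found by monotone bisection to 1e-6.

The scenario runner draws D datasets, applies the mechanism, runs
`n_replicates` replicate analyses per (approach, K) — each replicate
redraws both the fold partitions and the imputations, which is what makes
the between-replicate spread of approach 2 include fold-definition
variation and produce its characteristic plateau in R — and reports grand
means with Monte Carlo standard errors (sd / √D) across datasets.  A
failed dataset is recorded and excluded with a warning.

**Problem sizes.**  The package's default study profile is 10 datasets of
n = 500 with 5 replicates and K ∈ {1, 10, 50}; the full-scale design
(100 datasets of n = 1000, 10 replicates, K up to 100, plus K = 1000 in
the real-data protocol) is available behind the CLI's `--full` flag.  The
desk profile was chosen so the whole study runs in minutes on a single
core while leaving the qualitative contrasts (R decreasing in K for
prediction averaging; prediction averaging beating pooling; larger β₁
inflating R) clearly resolved.

## Randomness and reproducibility

All stochastic components draw from numpy Generators seeded through
SeedSequence spawn keys that encode the component's position:
(dataset, replicate, imputation pass k, fold j), with a reserved tag for
fold-partition draws.  Consequences: results are independent of execution
order and parallelism; replicate analyses are independent; approaches share
random numbers at equal seeds, so all three approaches coincide exactly at
K = 1 without any special-casing; and rerunning any analysis with the same
seed reproduces outputs byte-identically (CSV floats are written with 17
significant digits and parsed with round-trip precision).

## What the generator does and does not emulate

The synthetic cohorts have gaussian, moderately correlated predictors, a
correctly specified logistic outcome, and missingness confined to one
column under known MCAR/MAR mechanisms.  Real cohorts deviate in all four
respects: skewed and discrete predictors, model misspecification,
missingness scattered over several columns, and mechanisms that may be
missing-not-at-random.  Passing tests therefore demonstrate the internal
correctness and the comparative behaviour of the calibration strategies
under the stated generative conditions, not the absolute performance to
expect on any particular clinical dataset.  The leakage, reduction and
pooling guarantees, in contrast, are structural and hold for any input.

## Known limitations

* Chained equations has no general theoretical guarantee of a coherent
  joint model; the engine replicates standard practice rather than fixing
  its theory.
* Only cross-validation is implemented (a single set-aside validation set
  would be a straightforward variant); survival outcomes, variable
  selection, and Rubin pooling of performance estimates with standard
  errors are out of scope.
* Approach 3's mean-imputation rule for categorical predictors (modal
  level) is a convention; no canonical definition exists.
* The variation measure R is an ad hoc spread summary: it is informative on
  the probability scale but is not a variance estimate with sampling
  theory attached.
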