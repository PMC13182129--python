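# Methods

This note documents the statistical machinery in `shrinksim`: the models
and procedures, the assumptions behind the synthetic data, the numerical
choices, and the places where a genuinely open design decision was made.

## Shrinkage quantities

All three quantities attach to an unpenalised (maximum-likelihood)
logistic regression fitted on a development dataset of size `n` with `Q`
predictor parameters.

* **Optimal shrinkage `S_opt`** — the calibration slope of the fitted
  model in the target population, operationalised as the slope from a
  logistic regression of outcomes on the logit of predicted risks in a
  validation cohort large enough that sampling it is effectively sampling
  the population. A slope of 1 means the spread of the predictions is
  right; below 1 they are too extreme.
* **Heuristic shrinkage `S_vh = 1 - Q/LR`** — closed form, with `LR` the
  likelihood-ratio statistic against the intercept-only model. It can be
  negative (when `LR < Q`); no truncation is applied anywhere in the
  package, because the degenerate values are informative and the
  study-level exclusion rules need to see them.
* **Bootstrap uniform shrinkage `S_boot`** — the mean, over bootstrap
  resamples of the development data (resample size equal to the original
  `n`, the standard nonparametric bootstrap), of the calibration slope
  that the refitted model attains on the *original* data. A replicate
  whose resampled outcome is constant, or whose refit does not converge,
  is dropped from the mean and counted as a failure; per-replicate
  accounting lets the engines apply a scenario-level failure-rate rule
  (default: exclude the scenario when more than 5% of all refits failed).

Identities worth knowing (both are asserted in the test suite): the
apparent calibration slope of a model evaluated on its own training data
is exactly 1 (forced by the maximum-likelihood score equations), and a
model whose linear predictor is inflated by a factor k against a
correctly specified truth has `S_opt = 1/k` exactly.

## Synthetic data-generating mechanisms

A *scenario* freezes one draw of simulation parameters:

| parameter | distribution / default |
|---|---|
| measured predictors `Q_meas` | uniform integer 1..30 |
| unmeasured predictors `Q_unmeas` | uniform integer 1..30 (0 under the alternative mechanism) |
| coefficients `b_j` (log odds ratios) | Uniform(-0.5, 0.5) |
| outcome proportion `prop` | Uniform(0.05, 0.95); intercept = logit(prop) |
| development size `n_dev` | 100 + Weibull(shape 0.5, scale 2500), redrawn until <= 5000, rounded |
| predictor covariance | random correlation matrix, or the identity |

Datasets drawn from a scenario have multivariate-normal predictors with
mean zero and the scenario covariance; the true risk uses the full linear
predictor over measured *and* unmeasured predictors; outcomes are
Bernoulli. Models are fitted on the measured block only, so the unmeasured
block acts as structured irreducible noise. The Weibull shape of 0.5 makes
small development samples much more frequent than large ones, with a heavy
right tail — the regime where shrinkage matters.

**Random correlation matrices.** A q x q factor matrix with independent
standard-normal entries is drawn, its Gram matrix formed, and the result
rescaled to unit diagonal. This is positive semi-definite by construction
and induces random dependence between every pair of predictors; for large
q the typical pairwise correlation is modest (order 1/sqrt(q)).

**Alternative ("independent C") mechanism.** Under the default mechanism,
adding predictors mechanically raises the model's discrimination, which
confounds any attempt to attribute estimator bias to the predictor count
versus the C-statistic. The alternative mechanism removes the unmeasured
block, draws a target C-statistic from Uniform(0.55, 0.95), and rescales
the initial coefficient vector by a scalar k > 0 so the model attains that
target — making predictor count and discrimination independent by
construction. The rescaling exploits the fact that the population
C-statistic is monotone in a uniform scaling of the coefficients: k is
bracketed by doubling/halving from 1 and then solved by bisection, with
the C of each candidate evaluated on one large simulated covariate cohort
(default 100,000 rows) by *population-weighted concordance* — each
individual contributes event mass `p_i` and non-event mass `1 - p_i`
rather than a sampled outcome, which removes the binomial noise from the
search at no extra cost. The intercept is held at logit(prop), i.e. the
exact generating model, and the search stops within a C tolerance of
0.002.

**What the generator does not emulate.** All predictors are Gaussian;
there are no binary or skewed predictors, no missing data, no model or
variable selection, and the fitted model is always correctly specified up
to the omitted (unmeasured) block. Passing tests therefore speak to the
behaviour of the estimators under clean, well-specified conditions; real
datasets add misspecification on top.

## Logistic fitting and metrics

The fit is a Newton/IRLS iteration with analytic gradient and Hessian,
step-halving to keep the likelihood monotone, and a warm-start option
(used by the bootstrap loop, which starts each refit at the original fit).
Convergence requires the infinity norm of the score to fall below 1e-8
(the engines relax this to 1e-6 * sqrt(n) for million-row population fits,
where the criterion is otherwise needlessly far below the Monte-Carlo
noise floor); 100 iterations is the cap. A fit whose standardised
coefficient magnitude `|b_j| * sd(x_j)` exceeds 50 is flagged as separated.
Non-convergence and separation are *flags*, not errors — the engines count
them and the exclusion rules decide.

Predicted risks are clipped to [1e-12, 1 - 1e-12] before taking logits, so
overfit small-sample models with near-boundary predictions yield finite
calibration regressions. The C-statistic uses midranks (ties count one
half). The Cox-Snell R2 is `1 - exp(-LR/n)`, with values of `LR` in
(-1e-8, 0) clamped to zero as rounding noise. Note that for a binary
outcome this R2 is bounded above by `1 - exp(2 * ll0/n)` (at most 0.75 at
50% prevalence), which bounds where the analytic sample-size formula is
defined.

## Minimum sample-size procedures

**Analytic criterion.** `N = p / ((S-1) * ln(1 - R2/S))`, rounded up to
whole participants. It is linear in `p` and undefined when `R2 >= S`.

**C-statistic to R2 conversion.** When only an anticipated C-statistic
`C` and prevalence are available, the anticipated Cox-Snell R2 is obtained
by simulating the binormal equal-variance model: with
`sigma = sqrt(2) * PhiInv(C)`, linear-predictor values are N(0, sigma^2)
for non-events and N(sigma^2, sigma^2) for events — the construction under
which the implied outcome model is exactly logistic with slope 1 and the
C-statistic exactly `C`. Event counts are fixed at `round(prev * n)`
(default n = 1e6) to remove binomial noise in the prevalence; a logistic
model is fitted and `1 - exp(-LR/n)` returned. Monte-Carlo noise at the
default size is about +/-0.0005 on an R2 of 0.03.

**Simulation-based criterion.** The search targets the mean *optimal*
shrinkage directly. Its data-generating model: `p` independent
standard-normal predictors with equal coefficients, scaled so that the
*exact* population C-statistic of the true logistic model equals the
anticipated `C` at the anticipated prevalence. The exact calibration
matters: the binormal mapping `C = Phi(sigma/sqrt(2))` is only approximate
for a marginally normal linear predictor with Bernoulli outcomes, and the
approximation error grows with `C` (a model calibrated by the mapping to a
nominal 0.85 realises about 0.833). Both `sigma` and the intercept are
solved by Gauss-Hermite quadrature (301 nodes), the concordance again via
population weighting.

For a candidate size `n`, `M` development cohorts are simulated and
fitted, and each model's calibration slope is measured on a *fresh*
validation cohort (default 100,000 rows). Regenerating the validation
cohort per replicate matters: a single fixed cohort contributes a shared
calibration-slope offset with a standard deviation near 0.02, which would
shift the returned `n` by several percent; per-replicate cohorts turn that
offset into noise that averages out across `M`.

The search seeds itself at the analytic criterion's answer, brackets the
target mean slope by geometric expansion (factor 1.4), then bisects
geometrically until the bracket is within 2% of `n` (evaluation budget 40,
default `M = 500`). Because the mean-slope curve is shallow in `n`, the
final answer is not a single noisy midpoint: a replicate-weighted linear
fit through all evaluations within a window around the bracket pools their
Monte-Carlo information and its root is returned. The returned `n` is then
re-evaluated with replicates grown until the standard error of the mean
slope is at most half the tolerance (default tolerance 0.005, replicate
budget 10M); `converged` records whether the final mean slope is within
tolerance (plus twice its standard error) of the target. A search that
exhausts its budget, or a specification whose smallest admissible cohort
already overshoots the target, returns its best candidate with
`converged = False` rather than raising.

Residual seed-to-seed variation in the returned `n` is roughly 1-3% at the
default settings. Near `C = 0.6` the required `n` is very sensitive to the
anticipated discrimination — the signal is weak, so small changes in `C`
move the answer by tens of percent; sample-size planning in that regime
should treat the anticipated C-statistic with particular caution.

## Study engines

Per scenario, study 1 generates one validation cohort (default 1,000,000
rows; the scaled-down test runs use 40,000), fits the population model on
it for `C_pop` and `R2_pop`, then runs 250 iterations (tests: 30) of:
development draw, fit, heuristic and bootstrap shrinkage (default 200
bootstrap replicates; tests: 60), apparent C and R2, and `S_opt` on the
validation cohort. Per-scenario bias is the mean over iterations of
(estimate - `S_opt`); its sd uses divisor `n` (not `n-1`), matching the
reporting convention, and the Monte-Carlo standard error is
`sd / sqrt(iterations)`.

Study 2 computes, per scenario, the analytic size from `R2_pop` and the
simulation-based size from `C_pop` (with the realized validation
prevalence), both targeting shrinkage 0.9, then measures `S_opt` for
models developed at each size across iterations. Scenarios whose analytic
criterion is undefined, or whose computed size exceeds a configurable cap
(default 100,000), are excluded with a recorded reason; scenarios whose
simulation-based search did not converge are reported as their own
stratum, never silently dropped.

Exclusion rules (study 1): negative mean heuristic, bootstrap, or apparent
R2; mean bootstrap shrinkage above 2; bootstrap failure rate above 5%.
(Study 2): mean `S_opt` negative or above 2 in either arm. Summaries
report mean, sd and the 2.5/25/50/75/97.5 percentiles (linear
interpolation between order statistics) per C_pop stratum (width-0.05 bins
from 0.55 to 0.9) plus an overall row; Monte-Carlo-error summaries use the
50/90/99 percentiles.

**Seeding.** One master seed; each scenario's generation, validation
cohort and every iteration get independent streams derived as
`SeedSequence(master, spawn_key=(study, scenario, stream))`. Results are
therefore identical whether scenarios run serially or concurrently, and
any scenario can be re-run in isolation.

**Problem sizes in the shipped tests.** The acceptance-style tests run
study 1 at 50 scenarios x 30 iterations (bootstrap 60, validation 40,000)
and study 2 at 20 scenarios x 25 iterations, with the sample-size searches
at 250 replicates per evaluation — sizes chosen so the full suite runs on
a single CPU in well under half an hour while leaving the qualitative
contrasts (sign patterns by C_pop stratum, bootstrap-versus-heuristic
dominance, simulation-versus-analytic targeting) comfortably outside their
Monte-Carlo noise. The cross-scenario magnitudes at this scale are
noisier than at full scale and are not asserted numerically.

## Known limitations

* The simulation-based search assumes equal coefficients on independent
  Gaussian predictors; other coefficient patterns with the same population
  C shift the expected calibration slope slightly (of order 0.005 at
  realistic sizes), hence the returned `n` by a few percent.
* The bootstrap failure policy (drop-and-count per replicate) is one of
  several defensible conventions; the failure rate is recorded per
  scenario so a stricter all-or-nothing rule can be applied downstream.
* Very low discrimination (`C` below about 0.6) combined with few
  predictors produces unstable shrinkage estimates in both directions;
  results there depend strongly on the exclusion rules.
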