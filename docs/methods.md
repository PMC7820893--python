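# Methods

## Model

Integer BIMC scores `y` in {0, ..., 37} are mapped to the open unit
interval by the affine transformation `y' = 0.01 + 0.98 y / 37`, which
sends the attainable range [0, 37] onto [0.01, 0.99] and so keeps every
observation strictly inside the beta support.  The observation model is a
mean/precision-parameterized beta distribution,

    y'_ij | mu_ij, phi  ~  Beta(mu_ij phi, (1 - mu_ij) phi),

with mean `mu_ij` and variance `mu_ij (1 - mu_ij) / (1 + phi)`; `phi > 0`
is a precision parameter.  The mean follows a logit-linear predictor in
standardized age (optionally its square), sex (0 female / 1 male),
standardized years of education, APOE allele-group dummies (e3e3 as the
reference; e2 = {e2e2, e2e3}; e4 = {e3e4, e4e4}; e2e4 excluded), and the
two-way interactions age x education, age x APOE, education x APOE.

Within-participant correlation of repeated assessments is handled by a
piecewise random intercept: participants with two or more scores receive
`b_i0 ~ N(mu_b, sigma_b^2)`, while participants with a single score are
assigned the population mean `mu_b` directly (a single observation cannot
identify its own intercept, and roughly half the cohort contributes only
a baseline assessment).  The intercept never appears as a fixed-effect
column; `mu_b` plays that role.

Priors: `N(0, 1000)` (variance scale) on every fixed effect and on
`mu_b`; `Gamma(shape 1, scale 1)` — i.e. Exponential(1) — on `phi` and on
the random-intercept precision `1/sigma_b^2`.  These are weakly
informative on the logit scale; the prior-sensitivity utility refits
under variances 10 and 100 for the normal priors and gamma variance 100
(shape 1, scale 10) and reports shifts in posterior-SD units.

## Sampler

`sample_posterior` runs an adaptive Gaussian random-walk
Metropolis-within-Gibbs.  Update blocks per sweep: each fixed-effect
coordinate; `mu_b`; all random intercepts simultaneously (they are
conditionally independent given the other blocks, so element-wise
accept/reject is valid and vectorizes); `log phi`; and `log tau_b`
(`tau_b = 1/sigma_b^2`), the log transforms carrying the usual Jacobian.
Proposal scales adapt in batches of 50 sweeps toward ~30% acceptance
(within the 20-45% band that is efficient for one-dimensional random
walks) during the burn-in phase only; after burn-in the kernels are
frozen, so retained draws come from a fixed-kernel Markov chain.
Defaults are 3 chains, 8,000 adaptation/burn-in sweeps, and 4,000
retained iterations.  Initialization is deterministic and data-informed:
fixed effects at 0, `mu_b` at the logit of the sample mean of `y'`,
`phi` at its method-of-moments estimate, each `b_i0` at `mu_b`,
`sigma_b^2` at 1.  Chains are seeded as `seed + 1000003 * chain`, so a
single integer reproduces the full run.

Diagnostics: `gelman_rubin` computes the potential scale reduction
factor (split-chain by default; the estimate is floored at 1.0 since
values below 1 are finite-sample artifacts) and `autocorrelation` the
standard sample autocorrelation.

## Model selection

`compute_dic` evaluates the conditional DIC: the deviance is -2 times
the beta log likelihood given all parameters including the random
intercepts, `pD = Dbar - D(posterior mean)`, and `DIC = Dbar + pD`.  The
conditional (rather than marginal) plug-in matches the default behavior
of the Gibbs-sampling engines conventionally used for this model class.
A Monte-Carlo standard error for DIC is estimated from the spread of
per-chain DICs.

`backward_select` starts from the full hierarchical model and at each
step refits every sub-model obtained by removing one droppable term
(interactions drop before their parents; the age-squared term is treated
as a child of age), using the same sampler seed for every candidate in a
step so DIC differences are not dominated by seed noise.  The removal
that most decreases DIC is taken; the search stops when no removal
decreases DIC.  Exact ties break toward the higher-order term, then
alphabetically.  Because DIC tends to overfit, `refine_by_ci` then drops
terms whose equal-tailed 95% credible interval covers zero — except that
a main effect is retained whenever a surviving interaction contains it —
and the pruned model is refit once (`select_model` wires the two stages
together).

## Effect summaries

Fitted trajectories evaluate the linear predictor at a covariate profile
with `mu_b` as the intercept (a population-typical participant), apply
the inverse logit, and invert the score rescaling.  Since `mu` ranges
over (0, 1) while attainable scores end at 37, the inverse map ranges
over (-0.38, 37.37); fitted values are truncated to [0, 37].  Credible
bands are pointwise 2.5/50/97.5 percentiles of the per-draw fitted
values and inherit the range restriction draw by draw.  The age of onset
of moderate impairment is the age at which the fitted trajectory falls
through score 26, located by scanning a fine grid over the observed age
range (91-113 by default) for sign changes and polishing each bracket
with Brent root finding (tolerance far below the 0.01-year reporting
resolution); with an age-squared term both crossings are reported and
the descending one is flagged as the onset.  Crossings outside 91-113
are reported only when the caller widens the search range, and are
marked extrapolated.

Fit metrics on the 0-37 scale: `RSS = sum (obs - fit)^2` and explained
variance = regression sum of squares / total sum of squares.

## Gaussian comparator

`fit_lmm` fits the conventional random-intercept linear mixed model to
the raw 0-37 scores with the same covariates, by maximum likelihood
(statsmodels MixedLM, `reml=False`) so that likelihoods are comparable
across mean structures; REML would change variance-component estimates
slightly but none of the comparison conclusions.  Wald t and p values
use the normal approximation.  If no participant has repeated measures
the random-intercept variance is unidentifiable and the fit falls back
to OLS with `sigma_b^2` pinned at 0 (with a warning).  Confidence bands
for fitted values use a parametric bootstrap (default B = 1000):
responses are simulated from the fitted Gaussian model, the model is
refit, and 2.5/97.5 percentiles of the refitted values are taken.
`compare_models` reports RSS, explained variance and the number of
fitted values outside [0, 37] for both models; the LMM side uses
conditional fitted values (including predicted random intercepts) so
both models are compared on the same footing, while the marginal fitted
values used in trajectory figures are available separately and are the
ones that can escape the score range.

## Synthetic cohort generator

The generator emulates the structure of a longitudinal centenarian
cohort: truncated-normal enrollment ages (mean 103.3, SD 4.5, range
91-113), annual follow-up truncated at 113, a follow-up-count
distribution with 49% singletons, male fraction 0.25, a discrete
education distribution with quartiles 8/12/15 years (mean ~11.5), and
genotype composition with allele-group shares 117 : 331 : 38 plus a 4/768
admixture of e2e4 carriers.  Genotypes are assigned by quota
(largest-remainder counts, randomly permuted over participants) so that
the default 768-participant cohort contains exactly the published
exclusion classes for every seed; an independent-multinomial mode is
available for plain random sampling.  Outcomes are drawn from the model
above at configurable true parameters; the defaults are the published
final-model shape (intercept 0.592, age -0.110, sex 0.262, education
0.062, APOE2 0.037, APOE2 x edu -0.063, APOE4 -0.382, APOE4 x edu
-0.082) with `sigma_b = 0.5` and `phi = 6`, chosen once so that the
simulated baseline score distribution has mean ~24 and SD ~8, matching
the dispersion of the real cohort's summary statistics.  Continuous beta
draws are mapped to integer scores by inverting the rescaling and
rounding to the nearest integer in 0-37.  Missing scores and missing
education are injected on disjoint participant subsets drawn from
non-e2e4 carriers — score first, then education — which makes the
sequential exclusion accounting (768 - 167 - 111 - 4 = 486) exact.

What the generator does not emulate: mortality/dropout as a process
(only the singleton fraction), practice effects, proxy administration,
within-participant covariate drift, or any real linkage disequilibrium
structure behind the genotypes.  Tests passing on these cohorts
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to the misspecifications real data
would add.

## Numerical and design choices

- Standardization: age over all retained test administrations (age is
  time-varying), education over participants; constants are recorded in
  the analysis set so fitted curves can always be mapped back to raw
  years.  The age-squared column is the square of standardized age,
  keeping the onset-age inversion a quadratic in `z_age`.
- Exclusion order is fixed (missing score, then missing education, then
  e2e4) and each participant is attributed to the first applicable
  reason.
- `beta_logpdf` rejects boundary arguments rather than clamping them;
  the rescaling guarantees interior data.
- Problem sizes in the test suite: parameter recovery uses 5 replicate
  cohorts of 480 participants at the full default chain lengths;
  selection checks use 100-160 participants with shortened chains
  (shared seeds across candidates); these sizes give Monte-Carlo errors
  small enough for the assertions while keeping the suite quick.
- Known limitations: the sampler is random-walk based and would mix
  slowly for strongly correlated fixed effects (standardization keeps
  correlations modest); DIC is reported conditionally only; the
  bootstrap is parametric (model-based), not case-resampling.
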