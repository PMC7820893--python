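# cogbeta

Bayesian hierarchical beta regression for bounded longitudinal cognitive
test scores, with a synthetic centenarian-cohort generator and a
conventional linear mixed-model comparator.

## The problem

Global cognition screens such as the Blessed Information-Memory-
Concentration (BIMC) test produce integer scores on a fixed range (0-37)
whose distributions are bounded and skewed, especially in very old
cohorts.  The conventional analysis — a Gaussian random-intercept linear
mixed model — ignores the bounds: fitted trajectories and their confidence
bands can exceed the maximum attainable score, and the genetic effects of
interest (APOE allele group, and its interaction with education) are
estimated under a misspecified error law.

`cogbeta` implements the alternative: scores are rescaled onto
[0.01, 0.99] via `y' = 0.01 + 0.98 y / 37` and modelled as

```
y'_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)            Var = mu(1-mu)/(1+phi)
logit(mu_ij) = mu_b * I_single,i + b_i0 * (1 - I_single,i)
             + beta_age * age_ij + beta_age2 * age_ij^2
             + beta_sex * sex_i + beta_edu * edu_i + beta_APOE * APOE_i
             + interactions (age x edu, age x APOE, edu x APOE)
b_i0 ~ N(mu_b, sigma_b^2)
```

where `age` and `edu` are standardized, APOE genotypes collapse to allele
groups e2 = {e2e2, e2e3}, e3 = {e3e3} (reference), e4 = {e3e4, e4e4}
(e2e4 carriers are excluded), and the piecewise intercept assigns the
population mean `mu_b` to participants with a single assessment and a
participant-specific `b_i0` to those with repeats.  Priors are N(0, 1000)
on all fixed effects and `mu_b`, and Gamma(1, 1) on `phi` and on
`1/sigma_b^2`.  Inference is by an in-repo adaptive Metropolis-within-
Gibbs sampler (3 chains, 8,000 adaptation/burn-in sweeps + 4,000 retained
iterations by default), model search is DIC-driven backward elimination
refined by 95% credible intervals, and results are summarized as fitted
BIMC trajectories, credible bands, and ages of onset of moderate
impairment (score 26).

Because the motivating cohort data are access-restricted, the package
ships a first-class synthetic cohort generator
(`cogbeta.cohort.generate_cohort`) that emulates the real data structure —
enrollment ages 91-113, allele-group frequencies 117/331/38, education
quartiles 8/12/15 years, ~49% single-assessment participants, injectable
missingness and rare e2e4 genotypes — with outcomes drawn from the model
above at known true parameters, so every pipeline stage is testable
against ground truth.

## Worked example

```python
import numpy as np
from cogbeta import (
    necs_default_config, generate_cohort, apply_exclusions,
    build_analysis_set, build_design, ModelTerms,
    Priors, McmcConfig, sample_posterior,
)

cohort = generate_cohort(necs_default_config(seed=1))
_, log = apply_exclusions(cohort)
print(log)
# ExclusionLog(n_input=768, n_missing_score=167, n_missing_education=111,
#              n_e2e4=4, n_retained=486)

aset = build_analysis_set(cohort, contrast="e2_vs_e3")
terms = ModelTerms({"age", "sex", "edu", "apoe", "edu_x_apoe"})
design = build_design(aset, terms)
samples = sample_posterior(
    design, Priors(),
    McmcConfig(n_chains=2, n_adapt_burnin=2000, n_iter=2000, seed=7),
)
print(samples.summary().round(3))
#                  mean     sd  ci_0.025  ci_0.975
# parameter
# mu_b            0.560  0.047     0.473     0.658
# age            -0.099  0.033    -0.163    -0.033
# sex             0.398  0.083     0.241     0.564
# edu             0.043  0.038    -0.029     0.121
# group_e2        0.105  0.083    -0.049     0.274
# edu_x_group_e2  0.077  0.079    -0.077     0.226
# phi             6.013  0.294     5.437     6.605
# sigma2_b        0.285  0.050     0.198     0.393
```

The 768-participant synthetic cohort loses 167 participants to missing
scores, 111 to missing education and 4 to the ambiguous e2e4 genotype,
leaving 486.  The generating values were intercept 0.592, age -0.110,
sex 0.262, education 0.062, APOE2 0.037, APOE2-by-education -0.063,
phi 6, sigma_b^2 0.25: the strongly identified parameters (intercept,
age, sex, phi, sigma_b^2) land close to truth, while the allele-group
and interaction coefficients — informed only by the ~120 e2 carriers in
a single cohort of this size — carry wide credible intervals that still
cover the truth.  `cogbeta.effects` converts such draws into fitted 0-37
trajectories, credible bands and onset ages; `cogbeta.selection` runs the
DIC backward search with CI refinement; `cogbeta.lmm` fits the Gaussian
comparator and reports RSS and score-range violations side by side.

A `cogbeta` console script exposes the same stages
(`simulate`, `preprocess`, `fit`, `select`, `summarize`, `compare-lmm`);
see `cogbeta --help`.

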