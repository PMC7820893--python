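"""DIC, backward selection, CI refinement, prior sensitivity."""

import numpy as np
import pytest
from scipy.special import expit
from scipy import stats

from cogbeta.mcmc import McmcConfig, PosteriorSamples, Priors, sample_posterior
from cogbeta.preprocess import Design, ModelTerms, build_design
from cogbeta.selection import (
    DicResult,
    compute_dic,
    prior_sensitivity,
    refine_by_ci,
)


def _point_mass_samples(design, beta, mu_b, phi, n_iter=40):
    p = design.X.shape[1]
    n_rep = int((~design.singleton).sum())
    return PosteriorSamples(
        beta=np.tile(np.asarray(beta, float), (2, n_iter, 1)).reshape(2, n_iter, p),
        beta_names=list(design.columns),
        mu_b=np.full((2, n_iter), mu_b),
        phi=np.full((2, n_iter), phi),
        sigma2_b=np.full((2, n_iter), 0.5),
        b=np.full((2, n_iter, n_rep), mu_b),
        acceptance={},
        config=McmcConfig(n_chains=2, n_adapt_burnin=0, n_iter=max(n_iter, 1)),
        priors=Priors(),
    )


def _simple_design(rng, n=60, p=2):
    X = rng.normal(size=(n, p))
    y = rng.uniform(0.05, 0.95, size=n)
    return Design(
        X=X,
        columns=[f"x{j}" for j in range(p)],
        y=y,
        pid=np.arange(n),
        singleton=np.ones(n, dtype=bool),
        terms=ModelTerms(set()),
        contrast="e2_vs_e3",
    )


def test_dic_point_mass_posterior(rng):
    design = _simple_design(rng)
    samples = _point_mass_samples(design, [0.1, -0.2], 0.3, 4.0)
    res = compute_dic(samples, design)
    assert res.p_d == pytest.approx(0.0, abs=1e-9)
    assert res.dic == pytest.approx(res.d_at_mean, abs=1e-9)
    assert res.dic == pytest.approx(res.dbar + res.p_d, abs=1e-12)


def test_dic_invariant_to_draw_permutation(rng, small_design, quick_mcmc):
    samples = sample_posterior(small_design, Priors(), quick_mcmc)
    res1 = compute_dic(samples, small_design)
    perm = rng.permutation(samples.beta.shape[1])
    shuffled = PosteriorSamples(
        beta=samples.beta[:, perm],
        beta_names=samples.beta_names,
        mu_b=samples.mu_b[:, perm],
        phi=samples.phi[:, perm],
        sigma2_b=samples.sigma2_b[:, perm],
        b=samples.b[:, perm],
        acceptance=samples.acceptance,
        config=samples.config,
        priors=samples.priors,
    )
    res2 = compute_dic(shuffled, small_design)
    assert res1.dic == pytest.approx(res2.dic, abs=1e-8)
    assert res1.p_d == pytest.approx(res2.p_d, abs=1e-8)


def test_dic_effective_parameters_near_k_in_identified_model(rng):
    """On well-identified beta-regression data, p_D approximates the free
    parameter count (k fixed effects + intercept + phi)."""
    n, p = 800, 3
    X = rng.normal(size=(n, p))
    beta_true = np.array([0.5, -0.4, 0.3])
    mu = expit(0.2 + X @ beta_true)
    phi = 20.0
    y = rng.beta(mu * phi, (1 - mu) * phi)
    design = Design(
        X=X, columns=["x0", "x1", "x2"], y=y, pid=np.arange(n),
        singleton=np.ones(n, dtype=bool), terms=ModelTerms(set()), contrast="e2_vs_e3",
    )
    samples = sample_posterior(
        design, Priors(), McmcConfig(n_chains=2, n_adapt_burnin=1500, n_iter=1500, seed=3)
    )
    res = compute_dic(samples, design)
    k = p + 2  # betas + mu_b + phi
    assert res.p_d == pytest.approx(k, rel=0.30)


def test_dic_rejects_empty_samples(rng, small_design):
    samples = _point_mass_samples(small_design, np.zeros(5), 0.3, 4.0, n_iter=0)
    with pytest.raises(ValueError):
        compute_dic(samples, small_design)


def _samples_with_ci_shapes(design, spec_rows, n_iter=4000, seed=0):
    """Normal draws with given (mean, sd) per column, mirroring published
    posterior summaries."""
    rng = np.random.default_rng(seed)
    p = design.X.shape[1]
    beta = np.empty((2, n_iter, p))
    for j, name in enumerate(design.columns):
        mean, sd = spec_rows[name]
        beta[:, :, j] = rng.normal(mean, sd, size=(2, n_iter))
    n_rep = int((~design.singleton).sum())
    return PosteriorSamples(
        beta=beta,
        beta_names=list(design.columns),
        mu_b=rng.normal(0.592, 0.053, size=(2, n_iter)),
        phi=np.abs(rng.normal(6, 0.5, size=(2, n_iter))),
        sigma2_b=np.abs(rng.normal(0.3, 0.05, size=(2, n_iter))),
        b=np.zeros((2, n_iter, n_rep)),
        acceptance={},
        config=McmcConfig(n_chains=2, n_adapt_burnin=0, n_iter=n_iter),
        priors=Priors(),
    )


def test_refine_by_ci_drops_null_term_without_dependents(small_analysis_set):
    terms = ModelTerms({"age", "sex"})
    design = build_design(small_analysis_set, terms)
    samples = _samples_with_ci_shapes(
        design, {"age": (-0.11, 0.009), "sex": (0.05, 0.10)}
    )
    refined = refine_by_ci(samples, terms)
    assert "age" in refined and "sex" not in refined


def test_refine_by_ci_retains_clearly_nonzero_term(small_analysis_set):
    terms = ModelTerms({"edu"})
    design = build_design(small_analysis_set, terms)
    samples = _samples_with_ci_shapes(design, {"edu": (0.17, 0.03)})
    assert "edu" in refine_by_ci(samples, terms)


def test_refine_by_ci_keeps_main_effect_under_surviving_interaction(small_analysis_set):
    """Published retention pattern: the APOE2 main effect's CI spans 0
    (0.037, sd 0.088) but it stays because APOE2*edu (-0.063, sd 0.023)
    survives."""
    terms = ModelTerms({"age", "sex", "edu", "apoe", "edu_x_apoe"})
    design = build_design(small_analysis_set, terms)
    samples = _samples_with_ci_shapes(
        design,
        {
            "age": (-0.110, 0.009),
            "sex": (0.262, 0.096),
            "edu": (0.062, 0.012),
            "group_e2": (0.037, 0.088),
            "edu_x_group_e2": (-0.063, 0.023),
        },
    )
    refined = refine_by_ci(samples, terms)
    assert set(refined.included) == {"age", "sex", "edu", "apoe", "edu_x_apoe"}


def test_refine_by_ci_output_is_subset_and_hierarchical(small_analysis_set, quick_mcmc):
    terms = ModelTerms({"age", "sex", "edu", "apoe", "edu_x_apoe"})
    design = build_design(small_analysis_set, terms)
    samples = sample_posterior(design, Priors(), quick_mcmc)
    refined = refine_by_ci(samples, terms)
    assert refined.included <= terms.included
    ModelTerms(refined.included)  # would raise on hierarchy violation


def test_prior_sensitivity_single_setting_matches_base(small_analysis_set, quick_mcmc):
    terms = ModelTerms({"age", "edu"})
    table = prior_sensitivity(small_analysis_set, terms, [Priors()], config=quick_mcmc)
    assert (table["shift_sd"] == 0).all()
    assert set(table["parameter"]) == {"mu_b", "age", "edu", "phi", "sigma2_b"}


def test_prior_sensitivity_prior_dominates_tiny_data(small_cohort, quick_mcmc):
    """With ~10 participants the prior matters far more than with 240."""
    from cogbeta.preprocess import build_analysis_set

    ids = small_cohort["participant_id"].unique()[:10]
    tiny = small_cohort[small_cohort["participant_id"].isin(ids)]
    tiny_set = build_analysis_set(tiny, "e2_vs_e3")
    terms = ModelTerms({"age"})
    grid = [Priors(), Priors(beta_var=0.01, mu_b_var=0.01)]
    tiny_table = prior_sensitivity(tiny_set, terms, grid, config=quick_mcmc)
    big_table = prior_sensitivity(
        build_analysis_set(small_cohort, "e2_vs_e3"), terms, grid, config=quick_mcmc
    )
    fixed = ["mu_b", "age"]
    tiny_shift = tiny_table[tiny_table["parameter"].isin(fixed)]["shift_sd"].max()
    big_shift = big_table[big_table["parameter"].isin(fixed)]["shift_sd"].max()
    assert tiny_shift > big_shift
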