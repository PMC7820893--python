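"""Beta likelihood, log posterior, sampler, and convergence diagnostics."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from cogbeta.mcmc import (
    McmcConfig,
    Priors,
    autocorrelation,
    beta_logpdf,
    gelman_rubin,
    log_posterior,
    sample_posterior,
)
from cogbeta.preprocess import Design, ModelTerms


def test_beta_logpdf_uniform_case():
    # mu=0.5, phi=2 -> Beta(1,1), log density 0 everywhere
    assert beta_logpdf(0.3, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)


def test_beta_logpdf_closed_form_beta31():
    # mu=0.75, phi=4 -> Beta(3,1), density 3y^2; at y=0.5: log(3/4)
    assert beta_logpdf(0.5, 0.75, 4.0) == pytest.approx(np.log(0.75), abs=1e-10)


@pytest.mark.parametrize("mu,phi", [(0.2, 3.0), (0.5, 10.0), (0.9, 1.5)])
def test_beta_logpdf_matches_scipy_and_quadrature(mu, phi):
    y = np.linspace(0.01, 0.99, 23)
    ours = beta_logpdf(y, mu, phi)
    ref = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi)
    assert np.allclose(ours, ref, atol=1e-10)
    # quadrature check of the stated mean and variance
    m, _ = integrate.quad(lambda t: t * np.exp(beta_logpdf(t, mu, phi)), 0, 1)
    v, _ = integrate.quad(
        lambda t: (t - mu) ** 2 * np.exp(beta_logpdf(t, mu, phi)), 0, 1
    )
    assert m == pytest.approx(mu, abs=1e-8)
    assert v == pytest.approx(mu * (1 - mu) / (1 + phi), abs=1e-8)


def test_beta_logpdf_rejects_boundaries():
    for bad in [(0.0, 0.5, 2.0), (1.0, 0.5, 2.0), (0.5, 0.0, 2.0), (0.5, 0.5, -1.0)]:
        with pytest.raises(ValueError):
            beta_logpdf(*bad)


def _random_design(rng, n_part=8, p=3):
    n_visits = rng.integers(1, 4, size=n_part)
    pid = np.repeat(np.arange(n_part), n_visits)
    n = len(pid)
    X = rng.normal(size=(n, p))
    y = rng.uniform(0.05, 0.95, size=n)
    singleton = np.bincount(pid, minlength=n_part) == 1
    return Design(
        X=X,
        columns=[f"x{j}" for j in range(p)],
        y=y,
        pid=pid,
        singleton=singleton,
        terms=ModelTerms(set()),
        contrast="e2_vs_e3",
    )


def _oracle_log_posterior(params, design, priors):
    """Independent term-by-term summation using scipy.stats densities."""
    total = 0.0
    b_of = {}
    rep = np.flatnonzero(~design.singleton)
    for k, i in enumerate(rep):
        b_of[i] = params["b"][k]
        total += stats.norm.logpdf(params["b"][k], params["mu_b"], np.sqrt(params["sigma2_b"]))
    for r in range(len(design.y)):
        i = design.pid[r]
        intercept = b_of.get(i, params["mu_b"])
        eta = intercept + float(np.dot(design.X[r], params["beta"]))
        mu = expit(eta)
        total += stats.beta.logpdf(
            design.y[r], mu * params["phi"], (1 - mu) * params["phi"]
        )
    for bj in params["beta"]:
        total += stats.norm.logpdf(bj, 0, np.sqrt(priors.beta_var))
    total += stats.norm.logpdf(params["mu_b"], 0, np.sqrt(priors.mu_b_var))
    total += stats.gamma.logpdf(params["phi"], priors.phi_shape, scale=priors.phi_scale)
    total += stats.gamma.logpdf(
        1.0 / params["sigma2_b"], priors.tau_shape, scale=priors.tau_scale
    )
    return total


def test_log_posterior_matches_brute_force_oracle():
    rng = np.random.default_rng(77)
    priors = Priors()
    for _ in range(50):
        design = _random_design(rng, n_part=int(rng.integers(3, 10)), p=int(rng.integers(1, 4)))
        params = {
            "beta": rng.normal(size=design.X.shape[1]),
            "mu_b": float(rng.normal()),
            "b": rng.normal(size=int((~design.singleton).sum())),
            "phi": float(rng.uniform(0.5, 20)),
            "sigma2_b": float(rng.uniform(0.1, 4)),
        }
        ours = log_posterior(params, design, priors)
        assert ours == pytest.approx(_oracle_log_posterior(params, design, priors), abs=1e-10)


def test_log_posterior_zero_rows_equals_prior_sum():
    design = Design(
        X=np.empty((0, 2)),
        columns=["x0", "x1"],
        y=np.empty(0),
        pid=np.empty(0, dtype=int),
        singleton=np.ones(0, dtype=bool),
        terms=ModelTerms(set()),
        contrast="e2_vs_e3",
    )
    priors = Priors()
    params = {"beta": [0.3, -0.1], "mu_b": 0.2, "b": [], "phi": 2.0, "sigma2_b": 1.0}
    expected = (
        stats.norm.logpdf(0.3, 0, np.sqrt(1000))
        + stats.norm.logpdf(-0.1, 0, np.sqrt(1000))
        + stats.norm.logpdf(0.2, 0, np.sqrt(1000))
        + stats.expon.logpdf(2.0)
        + stats.expon.logpdf(1.0)
    )
    assert log_posterior(params, design, priors) == pytest.approx(expected, abs=1e-12)


def test_log_posterior_single_singleton_observation():
    design = Design(
        X=np.array([[1.5]]),
        columns=["x0"],
        y=np.array([0.7]),
        pid=np.array([0]),
        singleton=np.array([True]),
        terms=ModelTerms(set()),
        contrast="e2_vs_e3",
    )
    priors = Priors()
    params = {"beta": [0.2], "mu_b": 0.4, "b": [], "phi": 5.0, "sigma2_b": 1.0}
    mu = expit(0.4 + 0.2 * 1.5)
    expected = (
        stats.beta.logpdf(0.7, mu * 5, (1 - mu) * 5)
        + stats.norm.logpdf(0.2, 0, np.sqrt(1000))
        + stats.norm.logpdf(0.4, 0, np.sqrt(1000))
        + stats.expon.logpdf(5.0)
        + stats.expon.logpdf(1.0)
    )
    assert log_posterior(params, design, priors) == pytest.approx(expected, abs=1e-12)


def _intercept_only_design(rng, n=200, mu=0.6, phi=10.0):
    y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
    return Design(
        X=np.empty((n, 0)),
        columns=[],
        y=y,
        pid=np.arange(n),
        singleton=np.ones(n, dtype=bool),
        terms=ModelTerms(set()),
        contrast="e2_vs_e3",
    )


def test_sampler_recovers_intercept_only_mean():
    rng = np.random.default_rng(31)
    mu, phi, n = 0.6, 10.0, 200
    design = _intercept_only_design(rng, n=n, mu=mu, phi=phi)
    samples = sample_posterior(
        design, Priors(), McmcConfig(n_chains=2, n_adapt_burnin=1500, n_iter=1500, seed=13)
    )
    post_mu = expit(samples.mu_b.reshape(-1))
    se = np.sqrt(mu * (1 - mu) / (1 + phi) / n)
    assert abs(post_mu.mean() - mu) < 3 * se
    assert np.all(samples.phi > 0) and np.all(samples.sigma2_b > 0)


def test_sampler_is_deterministic_given_seed(small_design, quick_mcmc):
    a = sample_posterior(small_design, Priors(), quick_mcmc)
    b = sample_posterior(small_design, Priors(), quick_mcmc)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.phi, b.phi)
    assert np.array_equal(a.b, b.b)


def test_sampler_rejects_zero_iterations():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=0)


def test_default_run_lengths():
    cfg = McmcConfig()
    assert cfg.n_adapt_burnin >= 8000 and cfg.n_iter >= 4000 and cfg.n_chains == 3


def test_gelman_rubin_identical_chains():
    chain = np.random.default_rng(0).normal(size=500)
    assert gelman_rubin(np.stack([chain, chain]), split=False) == pytest.approx(1.0, abs=1e-12)


def test_gelman_rubin_separated_chains():
    rng = np.random.default_rng(1)
    chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert gelman_rubin(chains) > 1.1
    # direct-formula oracle (non-split)
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    expected = np.sqrt(((n - 1) / n * w + b / n) / w)
    assert gelman_rubin(chains, split=False) == pytest.approx(expected, rel=1e-12)


def test_gelman_rubin_affine_invariant():
    rng = np.random.default_rng(2)
    chains = rng.normal(size=(3, 400))
    r1 = gelman_rubin(chains)
    r2 = gelman_rubin(3.7 * chains - 11.0)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_gelman_rubin_matches_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    chains = rng.normal(size=(4, 600)) + 0.1 * np.arange(600)
    ours = gelman_rubin(chains, split=True)
    theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0], method="split"))
    assert ours == pytest.approx(theirs, rel=5e-3)


def test_gelman_rubin_requires_multiple_chains():
    with pytest.raises(ValueError):
        gelman_rubin(np.random.default_rng(0).normal(size=(1, 100)))


def test_autocorrelation_lag0_and_whitenoise():
    rng = np.random.default_rng(4)
    x = rng.normal(size=4000)
    assert autocorrelation(x, 0) == 1.0
    assert abs(autocorrelation(x, 1)) < 3 / np.sqrt(len(x))


def test_autocorrelation_ar1():
    rng = np.random.default_rng(5)
    n, rho = 20000, 0.8
    x = np.empty(n)
    x[0] = rng.normal()
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal()
    assert autocorrelation(x, 1) == pytest.approx(rho, abs=0.03)


def test_autocorrelation_degenerate_chain():
    with pytest.raises(ValueError, match="constant"):
        autocorrelation(np.ones(50), 1)
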