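"""Beta likelihood, priors, and MCMC for the hierarchical regression model.

The model for rescaled scores y'_ij in (0,1):

    y'_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)
    logit(mu_ij) = intercept_i + x_ij' beta
    intercept_i  = mu_b                    if participant i has one score
                 = b_i0 ~ N(mu_b, sigma_b^2)  otherwise

with priors beta_k, mu_b ~ N(0, 1000), and Gamma(1, 1) (= Exponential(1))
on the precision phi and on 1/sigma_b^2.  The sampler is an adaptive
Gaussian random-walk Metropolis-within-Gibbs over blocks (each fixed
effect, mu_b, the random intercepts jointly elementwise, log phi,
log tau_b); proposal scales adapt toward ~30% acceptance during burn-in
only, so the post-burn-in chain is a valid fixed-kernel Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from .preprocess import Design

__all__ = [
    "Priors",
    "McmcConfig",
    "PosteriorSamples",
    "beta_logpdf",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
    "autocorrelation",
]


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters.

    ``beta_var`` / ``mu_b_var`` are the variances of the zero-mean normal
    priors on fixed effects and on the random-intercept mean.  The gamma
    priors on phi and on the random-intercept precision tau_b = 1/sigma_b^2
    use the shape/scale parameterization; shape = scale = 1 is the
    Exponential(1) default.
    """

    beta_var: float = 1000.0
    mu_b_var: float = 1000.0
    phi_shape: float = 1.0
    phi_scale: float = 1.0
    tau_shape: float = 1.0
    tau_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_adapt_burnin: int = 8000
    n_iter: int = 4000
    adapt_batch: int = 50
    target_accept: float = 0.3
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be > 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_adapt_burnin < 0:
            raise ValueError("n_adapt_burnin must be >= 0")


def beta_logpdf(y, mu, phi):
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, with normalizer.

    Mean/precision parameterization: E[y] = mu, Var[y] = mu(1-mu)/(1+phi).
    Arguments must lie in the open ranges y, mu in (0,1), phi > 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return out.item() if out.ndim == 0 else out


def _normal_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _gamma_logpdf(x, shape, scale):
    return (
        -gammaln(shape)
        - shape * np.log(scale)
        + (shape - 1.0) * np.log(x)
        - x / scale
    )


@dataclass
class _State:
    beta: np.ndarray
    mu_b: float
    b: np.ndarray  # random intercepts for repeated-measure participants
    log_phi: float
    log_tau: float  # tau = 1/sigma_b^2


def log_posterior(params: dict, design: Design, priors: Priors) -> float:
    """Joint log posterior density (up to nothing — fully normalized terms).

    ``params`` maps ``"beta"`` -> array over design columns, ``"mu_b"`` ->
    float, ``"b"`` -> array over repeated-measure participants (ordered by
    participant index), ``"phi"`` and ``"sigma2_b"`` -> positive floats.
    """
    beta = np.asarray(params["beta"], dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError(
            f"beta has shape {beta.shape}, design expects ({design.X.shape[1]},)"
        )
    mu_b = float(params["mu_b"])
    b = np.asarray(params["b"], dtype=float)
    phi = float(params["phi"])
    sigma2_b = float(params["sigma2_b"])
    if phi <= 0 or sigma2_b <= 0:
        raise ValueError("phi and sigma2_b must be > 0")

    repeated = ~design.singleton
    if b.shape != (int(repeated.sum()),):
        raise ValueError("b must have one entry per repeated-measure participant")

    intercept_of = np.full(design.n_participants, mu_b)
    intercept_of[repeated] = b
    eta = intercept_of[design.pid] + (design.X @ beta if design.X.size else 0.0)
    mu = expit(eta)

    lp = 0.0
    if design.n_rows:
        lp += float(np.sum(beta_logpdf(design.y, mu, phi)))
    lp += float(np.sum(_normal_logpdf(b, mu_b, sigma2_b)))
    lp += float(np.sum(_normal_logpdf(beta, 0.0, priors.beta_var)))
    lp += float(_normal_logpdf(mu_b, 0.0, priors.mu_b_var))
    lp += float(_gamma_logpdf(phi, priors.phi_shape, priors.phi_scale))
    tau = 1.0 / sigma2_b
    lp += float(_gamma_logpdf(tau, priors.tau_shape, priors.tau_scale))
    return lp


@dataclass
class PosteriorSamples:
    """Post-burn-in draws, stacked per chain.

    ``beta`` has shape (n_chains, n_iter, p) in design-column order;
    ``mu_b``, ``phi``, ``sigma2_b`` have shape (n_chains, n_iter); ``b``
    has shape (n_chains, n_iter, n_repeated).
    """

    beta: np.ndarray
    beta_names: list[str]
    mu_b: np.ndarray
    phi: np.ndarray
    sigma2_b: np.ndarray
    b: np.ndarray
    acceptance: dict[str, float]
    config: McmcConfig
    priors: Priors

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled: fixed effect by column name or a scalar param."""
        if name in ("mu_b", "phi", "sigma2_b"):
            return getattr(self, name).reshape(-1)
        j = self.beta_names.index(name)
        return self.beta[:, :, j].reshape(-1)

    @property
    def param_names(self) -> list[str]:
        return ["mu_b", *self.beta_names, "phi", "sigma2_b"]

    def summary(self, level: float = 0.95):
        import pandas as pd

        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        for name in self.param_names:
            x = self.flat(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    f"ci_{lo:g}": np.quantile(x, lo),
                    f"ci_{hi:g}": np.quantile(x, hi),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def _rowsum_by_pid(values: np.ndarray, pid: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(pid, weights=values, minlength=n)


def sample_posterior(
    design: Design, priors: Priors = Priors(), config: McmcConfig = McmcConfig()
) -> PosteriorSamples:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    Blocks per sweep: each fixed-effect coordinate, mu_b, all random
    intercepts (element-wise, they are conditionally independent), log phi,
    log tau_b.  Proposal scales adapt in batches during burn-in and are
    frozen afterwards.  Deterministic given ``config.seed``.
    """
    if design.n_rows == 0:
        raise ValueError("design has no rows")
    p = design.X.shape[1]
    repeated = ~design.singleton
    rep_ids = np.flatnonzero(repeated)
    n_rep = len(rep_ids)
    # rows belonging to repeated-measure participants, with a compact index
    rep_pos = np.full(design.n_participants, -1)
    rep_pos[rep_ids] = np.arange(n_rep)
    row_rep = rep_pos[design.pid]  # -1 for singleton rows
    rep_rows = row_rep >= 0
    single_rows = ~rep_rows

    y = design.y
    log_y = np.log(y)
    log_1my = np.log1p(-y)

    def loglik_rows(eta, phi, mask=None):
        """Beta log likelihood of the masked rows given linear predictor."""
        if mask is not None:
            eta = eta[mask]
            ly, l1my = log_y[mask], log_1my[mask]
        else:
            ly, l1my = log_y, log_1my
        mu = expit(eta)
        a = mu * phi
        bb = phi - a
        return gammaln(phi) * len(ly) - np.sum(gammaln(a)) - np.sum(gammaln(bb)) + np.sum(
            (a - 1.0) * ly
        ) + np.sum((bb - 1.0) * l1my)

    def loglik_per_row(eta, phi, ly, l1my):
        mu = expit(eta)
        a = mu * phi
        bb = phi - a
        return gammaln(phi) - gammaln(a) - gammaln(bb) + (a - 1.0) * ly + (
            bb - 1.0
        ) * l1my

    # data-informed deterministic initialization
    ybar = float(np.mean(y))
    mu_b0 = float(logit(ybar))
    v = float(np.var(y))
    phi0 = max(ybar * (1 - ybar) / max(v, 1e-6) - 1.0, 0.5)

    chains_beta = []
    chains_mu_b = []
    chains_phi = []
    chains_s2 = []
    chains_b = []
    acc_totals: dict[str, list] = {}

    n_total = config.n_adapt_burnin + config.n_iter

    for chain in range(config.n_chains):
        rng = np.random.default_rng((config.seed + 1000003 * chain) % (2**31 - 1))
        st = _State(
            beta=np.zeros(p),
            mu_b=mu_b0,
            b=np.full(n_rep, mu_b0),
            log_phi=np.log(phi0),
            log_tau=0.0,
        )
        # proposal log-scales per block
        ls_beta = np.full(p, np.log(config.init_scale))
        ls_mu_b = np.log(config.init_scale)
        ls_b = np.log(config.init_scale * 2)
        ls_phi = np.log(config.init_scale)
        ls_tau = np.log(config.init_scale * 3)

        acc = {f"beta[{j}]": 0 for j in range(p)}
        acc.update({"mu_b": 0, "b": 0, "phi": 0, "tau": 0})
        batch_acc = dict.fromkeys(acc, 0)
        batch_n = dict.fromkeys(acc, 0)

        # cached quantities
        xb = design.X @ st.beta if p else np.zeros(design.n_rows)
        intercept_rows = np.where(single_rows, st.mu_b, 0.0)
        intercept_rows[rep_rows] = st.b[row_rep[rep_rows]]
        eta = intercept_rows + xb
        phi = np.exp(st.log_phi)
        cur_ll = loglik_rows(eta, phi)
        if not np.isfinite(cur_ll):
            raise RuntimeError("non-finite likelihood at initialization")

        keep_beta = np.empty((config.n_iter, p))
        keep_mu_b = np.empty(config.n_iter)
        keep_phi = np.empty(config.n_iter)
        keep_s2 = np.empty(config.n_iter)
        keep_b = np.empty((config.n_iter, n_rep))

        n_single_rows = int(np.sum(single_rows))

        for it in range(n_total):
            adapting = it < config.n_adapt_burnin

            # --- fixed-effect coordinates ---
            for j in range(p):
                step = rng.normal(0.0, np.exp(ls_beta[j]))
                eta_prop = eta + design.X[:, j] * step
                ll_prop = loglik_rows(eta_prop, phi)
                bj = st.beta[j]
                lr = (
                    ll_prop
                    - cur_ll
                    + _normal_logpdf(bj + step, 0.0, priors.beta_var)
                    - _normal_logpdf(bj, 0.0, priors.beta_var)
                )
                batch_n[f"beta[{j}]"] += 1
                if np.log(rng.random()) < lr:
                    st.beta[j] = bj + step
                    eta = eta_prop
                    cur_ll = ll_prop
                    acc[f"beta[{j}]"] += 1
                    batch_acc[f"beta[{j}]"] += 1

            # --- mu_b (affects singleton rows and the b prior) ---
            step = rng.normal(0.0, np.exp(ls_mu_b))
            mu_b_prop = st.mu_b + step
            sigma2 = np.exp(-st.log_tau)
            if n_single_rows:
                ll_old = loglik_rows(eta, phi, mask=single_rows)
                eta_prop_s = eta[single_rows] + step
                mu_s = expit(eta_prop_s)
                a = mu_s * phi
                bb = phi - a
                ll_new = (
                    gammaln(phi) * n_single_rows
                    - np.sum(gammaln(a))
                    - np.sum(gammaln(bb))
                    + np.sum((a - 1.0) * log_y[single_rows])
                    + np.sum((bb - 1.0) * log_1my[single_rows])
                )
            else:
                ll_old = ll_new = 0.0
            lr = (
                ll_new
                - ll_old
                + np.sum(_normal_logpdf(st.b, mu_b_prop, sigma2))
                - np.sum(_normal_logpdf(st.b, st.mu_b, sigma2))
                + _normal_logpdf(mu_b_prop, 0.0, priors.mu_b_var)
                - _normal_logpdf(st.mu_b, 0.0, priors.mu_b_var)
            )
            batch_n["mu_b"] += 1
            if np.log(rng.random()) < lr:
                st.mu_b = mu_b_prop
                if n_single_rows:
                    eta[single_rows] += step
                    cur_ll += ll_new - ll_old
                acc["mu_b"] += 1
                batch_acc["mu_b"] += 1

            # --- random intercepts, element-wise (conditionally independent) ---
            if n_rep:
                steps = rng.normal(0.0, np.exp(ls_b), size=n_rep)
                eta_prop_r = eta[rep_rows] + steps[row_rep[rep_rows]]
                ll_new_rows = loglik_per_row(
                    eta_prop_r, phi, log_y[rep_rows], log_1my[rep_rows]
                )
                ll_old_rows = loglik_per_row(
                    eta[rep_rows], phi, log_y[rep_rows], log_1my[rep_rows]
                )
                dll = _rowsum_by_pid(
                    ll_new_rows - ll_old_rows, row_rep[rep_rows], n_rep
                )
                b_prop = st.b + steps
                dprior = _normal_logpdf(b_prop, st.mu_b, sigma2) - _normal_logpdf(
                    st.b, st.mu_b, sigma2
                )
                accept_b = np.log(rng.random(n_rep)) < dll + dprior
                if np.any(accept_b):
                    st.b = np.where(accept_b, b_prop, st.b)
                    take = accept_b[row_rep[rep_rows]]
                    eta_r = eta[rep_rows]
                    eta_r[take] = eta_prop_r[take]
                    eta[rep_rows] = eta_r
                    cur_ll += float(np.sum(dll[accept_b]))
                batch_acc["b"] += float(np.mean(accept_b))
                batch_n["b"] += 1
                acc["b"] += float(np.mean(accept_b))

            # --- log phi ---
            step = rng.normal(0.0, np.exp(ls_phi))
            log_phi_prop = st.log_phi + step
            phi_prop = np.exp(log_phi_prop)
            ll_prop = loglik_rows(eta, phi_prop)
            # Gamma prior plus log-scale Jacobian
            lr = (
                ll_prop
                - cur_ll
                + _gamma_logpdf(phi_prop, priors.phi_shape, priors.phi_scale)
                - _gamma_logpdf(phi, priors.phi_shape, priors.phi_scale)
                + log_phi_prop
                - st.log_phi
            )
            batch_n["phi"] += 1
            if np.log(rng.random()) < lr:
                st.log_phi = log_phi_prop
                phi = phi_prop
                cur_ll = ll_prop
                acc["phi"] += 1
                batch_acc["phi"] += 1

            # --- log tau_b (precision of the random intercepts) ---
            step = rng.normal(0.0, np.exp(ls_tau))
            log_tau_prop = st.log_tau + step
            tau, tau_prop = np.exp(st.log_tau), np.exp(log_tau_prop)
            lr = (
                np.sum(_normal_logpdf(st.b, st.mu_b, 1.0 / tau_prop))
                - np.sum(_normal_logpdf(st.b, st.mu_b, 1.0 / tau))
                + _gamma_logpdf(tau_prop, priors.tau_shape, priors.tau_scale)
                - _gamma_logpdf(tau, priors.tau_shape, priors.tau_scale)
                + log_tau_prop
                - st.log_tau
            )
            batch_n["tau"] += 1
            if np.log(rng.random()) < lr:
                st.log_tau = log_tau_prop
                acc["tau"] += 1
                batch_acc["tau"] += 1

            # --- batch adaptation (burn-in only) ---
            if adapting and (it + 1) % config.adapt_batch == 0:
                delta = min(0.1, (it + 1) ** -0.5) * 2.0
                def _adjust(ls, key):
                    rate = batch_acc[key] / max(batch_n[key], 1)
                    return ls + (delta if rate > config.target_accept else -delta)

                for j in range(p):
                    ls_beta[j] = _adjust(ls_beta[j], f"beta[{j}]")
                ls_mu_b = _adjust(ls_mu_b, "mu_b")
                if n_rep:
                    ls_b = _adjust(ls_b, "b")
                ls_phi = _adjust(ls_phi, "phi")
                ls_tau = _adjust(ls_tau, "tau")
                batch_acc = dict.fromkeys(batch_acc, 0)
                batch_n = dict.fromkeys(batch_n, 0)

            if not adapting:
                k = it - config.n_adapt_burnin
                keep_beta[k] = st.beta
                keep_mu_b[k] = st.mu_b
                keep_phi[k] = phi
                keep_s2[k] = np.exp(-st.log_tau)
                keep_b[k] = st.b

        chains_beta.append(keep_beta)
        chains_mu_b.append(keep_mu_b)
        chains_phi.append(keep_phi)
        chains_s2.append(keep_s2)
        chains_b.append(keep_b)
        for key, v in acc.items():
            acc_totals.setdefault(key, []).append(v / n_total)

    return PosteriorSamples(
        beta=np.stack(chains_beta),
        beta_names=list(design.columns),
        mu_b=np.stack(chains_mu_b),
        phi=np.stack(chains_phi),
        sigma2_b=np.stack(chains_s2),
        b=np.stack(chains_b),
        acceptance={k: float(np.mean(v)) for k, v in acc_totals.items()},
        config=config,
        priors=priors,
    )


def gelman_rubin(chains, split: bool = True) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` is an (m, n) array of m chains.  With ``split=True`` each
    chain is halved first (detects within-chain trends); ``split=False``
    gives the classic between/within comparison, which equals 1.0 exactly
    for identical stationary chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains of equal length")
    if split:
        n2 = x.shape[1] // 2
        x = np.concatenate([x[:, :n2], x[:, n2 : 2 * n2]], axis=0)
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    # estimates below 1 are finite-sample artifacts; floor at the ideal value
    return max(float(np.sqrt(var_hat / w)), 1.0)


def autocorrelation(chain, lag: int) -> float:
    """Sample autocorrelation of a chain at the given lag (lag 0 -> 1)."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if lag < 0 or lag >= n:
        raise ValueError("lag must satisfy 0 <= lag < len(chain)")
    x = x - x.mean()
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant chain")
    if lag == 0:
        return 1.0
    return float(np.sum(x[:-lag] * x[lag:]) / denom)
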