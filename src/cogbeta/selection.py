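"""Model selection: DIC, backward search, CI refinement, prior sensitivity.

The search starts from the full fixed-effect structure (main effects, age
squared, all two-way interactions), repeatedly removes the droppable term
whose removal most decreases the deviance information criterion, and stops
when no removal helps.  Because DIC tends to overfit, the selected model is
then pruned by posterior credible intervals: terms whose equal-tailed 95%
CI covers 0 are dropped, except that a main effect is kept whenever a
surviving interaction contains it; one refit follows the pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import McmcConfig, PosteriorSamples, Priors, beta_logpdf, sample_posterior
from .preprocess import AnalysisSet, Design, ModelTerms, build_design

__all__ = [
    "DicResult",
    "SelectionStep",
    "SelectionTrace",
    "compute_dic",
    "backward_select",
    "refine_by_ci",
    "prior_sensitivity",
]


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion decomposition.

    dbar is the posterior-mean deviance, d_at_mean the deviance at the
    posterior mean of all parameters (conditional on the random
    intercepts), p_d = dbar - d_at_mean the effective parameter count, and
    dic = dbar + p_d.  ``mc_se`` estimates the Monte-Carlo standard error
    of dic from the spread of per-chain DICs.
    """

    dbar: float
    d_at_mean: float
    p_d: float
    dic: float
    mc_se: float = np.nan


def _deviance(design: Design, beta, mu_b, b, phi) -> float:
    """-2 x beta log likelihood given all parameters (conditional)."""
    intercept = np.full(design.n_participants, mu_b)
    intercept[~design.singleton] = b
    eta = intercept[design.pid]
    if design.X.size:
        eta = eta + design.X @ beta
    mu = expit(eta)
    return -2.0 * float(np.sum(beta_logpdf(design.y, mu, phi)))


def compute_dic(samples: PosteriorSamples, design: Design) -> DicResult:
    """Conditional DIC from posterior draws.

    The likelihood part is the beta likelihood only; the plug-in point is
    the posterior mean of every parameter including the random intercepts.
    """
    n_chains, n_iter, p = samples.beta.shape
    if n_iter == 0:
        raise ValueError("empty samples")
    if p != design.X.shape[1]:
        raise ValueError("samples and design have inconsistent dimensions")

    dev = np.empty((n_chains, n_iter))
    for c in range(n_chains):
        for k in range(n_iter):
            dev[c, k] = _deviance(
                design,
                samples.beta[c, k],
                samples.mu_b[c, k],
                samples.b[c, k],
                samples.phi[c, k],
            )
    dbar = float(dev.mean())
    d_at_mean = _deviance(
        design,
        samples.beta.reshape(n_chains * n_iter, p).mean(axis=0),
        float(samples.mu_b.mean()),
        samples.b.reshape(n_chains * n_iter, -1).mean(axis=0),
        float(samples.phi.mean()),
    )
    p_d = dbar - d_at_mean
    if n_chains >= 2:
        per_chain = 2.0 * dev.mean(axis=1) - d_at_mean  # dbar_c + (dbar_c - dhat)
        mc_se = float(per_chain.std(ddof=1) / np.sqrt(n_chains))
    else:
        mc_se = np.nan
    return DicResult(dbar, d_at_mean, p_d, dbar + p_d, mc_se)


@dataclass(frozen=True)
class SelectionStep:
    terms: ModelTerms
    dic: DicResult
    decision: str


@dataclass
class SelectionTrace:
    steps: list
    final_terms: ModelTerms
    final_samples: PosteriorSamples
    final_dic: DicResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "terms": ["+".join(s.terms) if len(s.terms) else "(intercept)" for s in self.steps],
                "dic": [s.dic.dic for s in self.steps],
                "p_d": [s.dic.p_d for s in self.steps],
                "decision": [s.decision for s in self.steps],
            }
        )


def _fit(analysis_set: AnalysisSet, terms: ModelTerms, priors: Priors, config: McmcConfig):
    design = build_design(analysis_set, terms)
    samples = sample_posterior(design, priors, config)
    return design, samples


def backward_select(
    full: ModelTerms,
    analysis_set: AnalysisSet,
    priors: Priors = Priors(),
    config: McmcConfig = McmcConfig(),
) -> SelectionTrace:
    """DIC-driven backward elimination from the full model.

    At each step every droppable term (one whose removal keeps the model
    hierarchical — interactions go before their parents) is tried with the
    same sampler seed, and the removal that most decreases DIC is taken;
    the search stops when no removal decreases DIC.  Exact ties are broken
    toward the higher-order term, then alphabetically.
    """
    steps: list[SelectionStep] = []
    current = full
    design, samples = _fit(analysis_set, current, priors, config)
    current_dic = compute_dic(samples, design)
    steps.append(SelectionStep(current, current_dic, "start"))

    while True:
        droppable = current.droppable()
        if not droppable:
            break
        candidates = []
        for term in droppable:
            reduced = current.drop(term)
            d, s = _fit(analysis_set, reduced, priors, config)
            dic = compute_dic(s, d)
            steps.append(SelectionStep(reduced, dic, f"try drop {term}"))
            # on exact ties interactions (more parents) drop first
            candidates.append((dic.dic, -len(current.parents_of(term)), term, reduced, s, d, dic))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        best = candidates[0]
        if best[0] < current_dic.dic:
            current, samples, design, current_dic = best[3], best[4], best[5], best[6]
            steps.append(SelectionStep(current, current_dic, f"drop {best[2]}"))
        else:
            break

    return SelectionTrace(steps, current, samples, current_dic)


def _ci_excludes_zero(samples: PosteriorSamples, name: str, level: float) -> bool:
    x = samples.flat(name)
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
    return lo > 0 or hi < 0


def refine_by_ci(
    samples: PosteriorSamples, terms: ModelTerms, level: float = 0.95
) -> ModelTerms:
    """Prune terms whose equal-tailed CI covers 0, respecting hierarchy.

    A term survives if any of its design columns has a CI excluding zero
    (the APOE term expands to one column per non-reference group), or if a
    surviving interaction requires it as a parent.
    """
    col_of = {}
    for name in samples.beta_names:
        key = name.replace("group_e2", "apoe").replace("group_e4", "apoe")
        col_of.setdefault(key, []).append(name)

    significant = set()
    for term in terms:
        cols = col_of.get(term, [])
        if any(_ci_excludes_zero(samples, c, level) for c in cols):
            significant.add(term)
    keep = set(significant)
    for term in significant:
        keep.update(terms.parents_of(term))
    return ModelTerms(keep & set(terms.included))


def select_model(
    analysis_set: AnalysisSet,
    full: ModelTerms = ModelTerms(),
    priors: Priors = Priors(),
    config: McmcConfig = McmcConfig(),
    level: float = 0.95,
) -> SelectionTrace:
    """Full two-stage selection: DIC backward search, then CI pruning with
    a single refit of the pruned model."""
    trace = backward_select(full, analysis_set, priors, config)
    pruned = refine_by_ci(trace.final_samples, trace.final_terms, level)
    if set(pruned.included) != set(trace.final_terms.included):
        design, samples = _fit(analysis_set, pruned, priors, config)
        dic = compute_dic(samples, design)
        trace.steps.append(SelectionStep(pruned, dic, "CI refinement"))
        trace.final_terms = pruned
        trace.final_samples = samples
        trace.final_dic = dic
    return trace


def default_prior_grid() -> list[Priors]:
    """The sensitivity grid: normal prior variance 1000 -> 100 -> 10 and
    gamma prior variance 1 -> 100 (shape 1, scale 10)."""
    return [
        Priors(),
        Priors(beta_var=100.0, mu_b_var=100.0),
        Priors(beta_var=10.0, mu_b_var=10.0),
        Priors(phi_scale=10.0, tau_scale=10.0),
    ]


def prior_sensitivity(
    analysis_set: AnalysisSet,
    terms: ModelTerms,
    prior_grid: list[Priors] | None = None,
    config: McmcConfig = McmcConfig(),
) -> pd.DataFrame:
    """Refit one model under each prior setting and tabulate the shifts.

    Returns a tidy table of posterior mean / sd / CI per parameter per
    prior setting, plus ``shift_sd`` — the absolute difference from the
    first (reference) setting in units of the reference posterior SD.
    """
    if prior_grid is None:
        prior_grid = default_prior_grid()
    if not prior_grid:
        raise ValueError("prior grid is empty")
    frames = []
    ref = None
    for i, priors in enumerate(prior_grid):
        _, samples = _fit(analysis_set, terms, priors, config)
        summ = samples.summary().reset_index()
        summ.insert(0, "prior", i)
        summ["beta_var"] = priors.beta_var
        summ["phi_scale"] = priors.phi_scale
        if ref is None:
            ref = summ.set_index("parameter")[["mean", "sd"]]
            summ["shift_sd"] = 0.0
        else:
            cur = summ.set_index("parameter")
            shift = (cur["mean"] - ref["mean"]).abs() / ref["sd"]
            summ["shift_sd"] = shift.to_numpy()
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)
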