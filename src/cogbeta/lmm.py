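"""Gaussian random-intercept linear mixed model comparator.

The conventional analysis of longitudinal test scores: the observed 0-37
scores (not rescaled) are regressed on the same covariates as the beta
model, with a participant random intercept.  Estimation is maximum
likelihood (not REML) via statsmodels MixedLM, so likelihoods are
comparable across mean structures.  Because the Gaussian model ignores the
score bounds, its fitted values and confidence bands can stray outside
[0, 37] — the comparison report counts such violations for both models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import residual_sum_squares
from .preprocess import AnalysisSet, Design, ModelTerms, build_design

__all__ = [
    "LmmFit",
    "fit_lmm",
    "lmm_fitted_values",
    "bootstrap_fitted_ci",
    "compare_models",
]


@dataclass
class LmmFit:
    """Fitted random-intercept linear mixed model (score scale)."""

    params: pd.Series  # fixed effects incl. "intercept"
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series  # z/normal approximation
    sigma2_b: float  # random-intercept variance
    sigma2_e: float  # residual variance
    loglike: float
    columns: list
    converged: bool
    all_singletons: bool = False
    #: conditional fitted values (X beta-hat + predicted random intercepts)
    fitted_conditional: np.ndarray | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "sd": self.bse,
                "t_value": self.tvalues,
                "p_value": self.pvalues,
            }
        )


def _fit_mixedlm(y, X, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            return model.fit(reml=False)
        except np.linalg.LinAlgError:
            return model.fit(reml=False, method="powell")


def _lmm_matrices(design: Design):
    X = np.column_stack([np.ones(design.n_rows), design.X])
    names = ["intercept", *design.columns]
    # response on the raw score scale
    y = (design.y - 0.01) / 0.98 * 37.0
    return X, names, y


def fit_lmm(design: Design) -> LmmFit:
    """ML fit of score ~ fixed effects + (1 | participant).

    If no participant has repeated measures the random-intercept variance
    is unidentifiable; the fit falls back to OLS with sigma2_b pinned at 0
    and a warning.  Singular fixed-effect designs are rejected with the
    offending columns named.
    """
    X, names, y = _lmm_matrices(design)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns by incremental rank
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"singular design; dependent columns: {bad}")

    if bool(design.singleton.all()):
        warnings.warn(
            "no repeated measures: random-intercept variance pinned at 0 (OLS fit)",
            stacklevel=2,
        )
        ols = sm.OLS(y, X).fit()
        resid_var = float(ols.ssr / len(y))  # ML variance
        se = ols.bse * np.sqrt(ols.df_resid / len(y))
        tvals = ols.params / se
        return LmmFit(
            params=pd.Series(ols.params, index=names),
            bse=pd.Series(se, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(2 * stats.norm.sf(np.abs(tvals)), index=names),
            sigma2_b=0.0,
            sigma2_e=resid_var,
            loglike=float(ols.llf),
            columns=names,
            converged=True,
            all_singletons=True,
            fitted_conditional=np.asarray(ols.fittedvalues),
        )

    res = _fit_mixedlm(y, X, design.pid)
    tvals = res.fe_params / res.bse_fe
    return LmmFit(
        params=pd.Series(res.fe_params, index=names),
        bse=pd.Series(np.asarray(res.bse_fe), index=names),
        tvalues=pd.Series(np.asarray(tvals), index=names),
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(np.asarray(tvals))), index=names),
        sigma2_b=float(np.asarray(res.cov_re)[0, 0]),
        sigma2_e=float(res.scale),
        loglike=float(res.llf),
        columns=names,
        converged=bool(res.converged),
        fitted_conditional=np.asarray(res.fittedvalues),
    )


def lmm_fitted_values(fit: LmmFit, design: Design) -> np.ndarray:
    """Marginal fitted scores X beta-hat (population level, no BLUPs)."""
    X, _, _ = _lmm_matrices(design)
    return X @ fit.params.to_numpy()


def bootstrap_fitted_ci(
    fit: LmmFit,
    design: Design,
    profile_X: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.05,
):
    """Parametric-bootstrap 95% bands for fitted values at profile rows.

    Simulates responses from the fitted Gaussian model (random intercept +
    residual noise), refits, and recomputes fitted values at the rows of
    ``profile_X`` (including the leading intercept column).  Returns
    (lower, upper) 2.5/97.5 percentile bands; reproducible by seed.
    Aborts if more than ``max_failure_rate`` of refits fail.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    X, names, _ = _lmm_matrices(design)
    rng = np.random.default_rng(seed)
    mean = X @ fit.params.to_numpy()
    n_part = design.n_participants
    out = np.empty((B, profile_X.shape[0]))
    failures = 0
    for b in range(B):
        u = rng.normal(0.0, np.sqrt(max(fit.sigma2_b, 0.0)), size=n_part)
        e = rng.normal(0.0, np.sqrt(fit.sigma2_e), size=len(mean))
        y_sim = mean + u[design.pid] + e
        try:
            if fit.all_singletons:
                params = np.linalg.lstsq(X, y_sim, rcond=None)[0]
            else:
                res = _fit_mixedlm(y_sim, X, design.pid)
                params = np.asarray(res.fe_params)
            out[b] = profile_X @ params
        except Exception:
            failures += 1
            out[b] = np.nan
    if failures > max_failure_rate * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    lower, upper = np.nanpercentile(out, [2.5, 97.5], axis=0)
    return lower, upper


def compare_models(
    beta_fitted: np.ndarray,
    lmm_fit: LmmFit,
    design: Design,
) -> dict:
    """Head-to-head report of the beta model and the LMM on one design.

    ``beta_fitted`` are the beta-model fitted scores (0-37 scale) for the
    rows of ``design``.  Reports RSS and explained variance for both
    models and how many fitted values fall outside [0, 37] for each.
    Conditional fitted values (including the participant intercepts) are
    used for the LMM when available, so both models are compared on the
    same footing.
    """
    beta_fitted = np.asarray(beta_fitted, dtype=float)
    if beta_fitted.shape != design.y.shape:
        raise ValueError("beta_fitted does not match the design rows")
    observed = (design.y - 0.01) / 0.98 * 37.0
    if lmm_fit.fitted_conditional is not None:
        lmm_fitted = np.asarray(lmm_fit.fitted_conditional, dtype=float)
        if lmm_fitted.shape != design.y.shape:
            raise ValueError("lmm_fit was computed on a different design")
    else:
        lmm_fitted = lmm_fitted_values(lmm_fit, design)

    def ev(fitted):
        obar = observed.mean()
        return float(np.sum((fitted - obar) ** 2) / np.sum((observed - obar) ** 2))

    def out_of_range(fitted):
        return int(np.sum((fitted < 0.0) | (fitted > 37.0)))

    return {
        "rss_beta": residual_sum_squares(beta_fitted, observed),
        "rss_lmm": residual_sum_squares(lmm_fitted, observed),
        "explained_variance_beta": ev(beta_fitted),
        "explained_variance_lmm": ev(lmm_fitted),
        "out_of_range_beta": out_of_range(beta_fitted),
        "out_of_range_lmm": out_of_range(lmm_fitted),
        "n_rows": design.n_rows,
    }
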