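"""Statistical models for firing-rate tables.

Two analysis chains:

* 1 s mean rates — rate ~ stimulus x location GLMs fit under Gamma,
  inverse-Gaussian and Gaussian families, compared by AIC (firing rates are
  positive and right-skewed, so Gamma typically wins); type-II Wald tests
  per term; estimated-marginal-mean pairwise stimulus contrasts within each
  location, Tukey-adjusted.

* 100 ms binned counts over 2 s — a Gamma/log mixed model on count + 1
  (the offset absorbs empty bins) with stimulus, time and their interaction
  as fixed effects and bee identity as a random intercept, plus per-time
  pairwise stimulus contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import chi2, studentized_range

from .glmm import GammaGLMMResult, fit_gamma_glmm

__all__ = [
    "RateModelReport",
    "TemporalModelReport",
    "select_rate_family",
    "wald_terms",
    "pairwise_marginal_means",
    "fit_temporal_glmm",
]

RATE_FORMULA = "rate_1s ~ C(stimulus) * C(location)"
#: strictly positive stand-in for zero rates under Gamma/inverse-Gaussian
ZERO_RATE_OFFSET = 0.5


@dataclass
class RateModelReport:
    """AIC family comparison plus the winning fitted model."""

    family: str
    aics: dict[str, float]
    model: object = field(repr=False)
    wald: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None


@dataclass
class TemporalModelReport:
    """Gamma mixed-model fit of binned counts."""

    result: GammaGLMMResult = field(repr=False)
    wald: pd.DataFrame
    pairwise: pd.DataFrame
    used_fallback: bool = False


_FAMILIES = {
    "Gamma": lambda: sm.families.Gamma(link=sm.families.links.Log()),
    "InverseGaussian": lambda: sm.families.InverseGaussian(
        link=sm.families.links.Log()
    ),
    "Gaussian": lambda: sm.families.Gaussian(),
}


def select_rate_family(table: pd.DataFrame, formula: str = RATE_FORMULA) -> RateModelReport:
    """Fit the rate GLM under each candidate family and pick the lowest AIC.

    Gamma and inverse-Gaussian use a log link, Gaussian an identity link.
    Zero rates are replaced by 0.5 spikes/s (with a warning) so the
    positive-support families remain usable.
    """
    if table["stimulus"].nunique() < 2:
        raise ValueError("need at least two stimuli to model stimulus effects")
    if table["location"].nunique() < 2:
        raise ValueError("need both sensillum locations (mid and tip)")
    data = table.copy()
    n_zero = int((data["rate_1s"] <= 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero rates replaced by {ZERO_RATE_OFFSET} spikes/s for "
            "positive-support families"
        )
        data.loc[data["rate_1s"] <= 0, "rate_1s"] = ZERO_RATE_OFFSET
    fits, aics = {}, {}
    for name, make in _FAMILIES.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm(formula, data=data, family=make()).fit()
        fits[name] = fit
        aics[name] = float(fit.aic)
    best = min(aics, key=aics.get)
    return RateModelReport(family=best, aics=aics, model=fits[best])


def _term_factors(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def wald_terms(result) -> pd.DataFrame:
    """Type-II Wald chi-square tests for each model term.

    Each term is tested in the model containing every term that does not
    marginally contain it (so main effects are tested after the other main
    effects but ignoring their interactions, matching type-II ANOVA
    conventions); interactions are tested in the full model.
    """
    model = result.model
    design_info = model.data.design_info
    terms = [t for t in design_info.term_names if t != "Intercept"]
    data = model.data.frame
    yname = model.endog_names
    rows = []
    for term in terms:
        fac = _term_factors(term)
        keep = [t for t in terms if not (_term_factors(t) > fac)]
        if set(keep) == set(terms):
            fit, di = result, design_info
        else:
            reduced = f"{yname} ~ {' + '.join(keep)}"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.glm(reduced, data=data, family=model.family).fit()
            di = fit.model.data.design_info
        sl = di.term_name_slices[term]
        k = len(fit.params)
        L = np.eye(k)[sl]
        if np.linalg.matrix_rank(L @ fit.cov_params() @ L.T) < L.shape[0]:
            raise ValueError(f"term {term!r} is aliased (singular design)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = fit.wald_test(L, scalar=True, use_f=False)
        rows.append(
            {
                "term": term,
                "chi2": float(test.statistic),
                "df": int(L.shape[0]),
                "p": float(test.pvalue),
            }
        )
    return pd.DataFrame(rows)


def _emm_grid(design_info, grid: pd.DataFrame) -> np.ndarray:
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat)


def _tukey_p(t: float, k: int, df: float) -> float:
    if k < 2:
        return np.nan
    df = max(df, 1.0)
    return float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))


def pairwise_marginal_means(
    result,
    by: str = "location",
    factor: str = "stimulus",
) -> pd.DataFrame:
    """Estimated-marginal-mean contrasts on the link scale.

    Within each level of ``by``, all pairwise differences between ``factor``
    levels are reported with Tukey family-wise adjusted p-values; between
    ``by``-level differences are reported per ``factor`` level (each its own
    two-member family, so the adjusted p equals the unadjusted one).
    """
    model = result.model
    design_info = model.data.design_info
    data = model.data.frame
    beta = np.asarray(result.params)
    cov = np.asarray(result.cov_params())
    df_resid = float(result.df_resid)

    f_levels = sorted(data[factor].unique())
    b_levels = sorted(data[by].unique())
    grid = pd.DataFrame(
        [(f, b) for b in b_levels for f in f_levels], columns=[factor, by]
    )
    R = _emm_grid(design_info, grid)
    rows = []
    k = len(f_levels)
    for b in b_levels:
        idx = {f: i for i, (f, bb) in enumerate(zip(grid[factor], grid[by])) if bb == b}
        for i, f1 in enumerate(f_levels):
            for f2 in f_levels[i + 1 :]:
                c = R[idx[f1]] - R[idx[f2]]
                est = float(c @ beta)
                se = float(np.sqrt(c @ cov @ c))
                t = est / se if se > 0 else np.nan
                rows.append(
                    {
                        "contrast": f"{f1} - {f2}",
                        "by": b,
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "p_unadj": float(chi2.sf(t**2, 1)) if np.isfinite(t) else np.nan,
                        "p_adj": _tukey_p(t, k, df_resid),
                        "family": f"{factor} within {by}={b}",
                    }
                )
    if len(b_levels) == 2:
        idx_map = {
            (f, bb): i for i, (f, bb) in enumerate(zip(grid[factor], grid[by]))
        }
        for f in f_levels:
            c = R[idx_map[(f, b_levels[0])]] - R[idx_map[(f, b_levels[1])]]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.nan
            p = float(chi2.sf(t**2, 1)) if np.isfinite(t) else np.nan
            rows.append(
                {
                    "contrast": f"{b_levels[0]} - {b_levels[1]}",
                    "by": f,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_unadj": p,
                    "p_adj": p,
                    "family": f"{by} within {factor}={f}",
                }
            )
    df = pd.DataFrame(rows)
    # family-wise adjustment can never report smaller p than the raw test
    df["p_adj"] = np.where(
        df["p_adj"].isna() | (df["p_adj"] < df["p_unadj"]), df["p_unadj"], df["p_adj"]
    )
    return df


def _glmm_wald(fit: GammaGLMMResult, term: str) -> tuple[float, int, float]:
    sl = fit.design_info.term_name_slices[term]
    idx = np.arange(len(fit.params))[sl]
    b = fit.params[idx]
    V = fit.cov_params[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return stat, df, float(chi2.sf(stat, df))


def fit_temporal_glmm(
    table: pd.DataFrame,
    formula: str = "count_plus_one ~ C(stimulus) * time_c",
    groups: str = "bee_id",
) -> TemporalModelReport:
    """Fit the temporal Gamma mixed model to binned counts.

    ``table`` needs columns bee_id, stimulus, time_bin (1..20) and
    count_plus_one (>= 1).  Time enters as a centred, scaled covariate
    time_c = (time_bin - 10.5) / 19.  Type-II Wald tests are reported for
    stimulus, time and their interaction (main effects tested in the
    additive refit), plus Tukey-adjusted pairwise stimulus contrasts at each
    time bin.  If the Laplace fit fails to converge the model falls back to
    a fixed-effects Gamma GLM and the report is flagged.
    """
    counts = table.groupby(["bee_id", "stimulus"])["time_bin"].nunique()
    if (counts != 20).any():
        bad = counts[counts != 20].index.tolist()
        raise ValueError(f"expected 20 bins per (bee, stimulus); offending: {bad}")
    data = table.copy()
    data["time_c"] = (data["time_bin"] - 10.5) / 19.0

    used_fallback = False
    try:
        full = fit_gamma_glmm(formula, data, groups=groups)
        if not full.converged:
            raise RuntimeError("Laplace fit did not converge")
        additive = fit_gamma_glmm(
            formula.replace("*", "+"), data, groups=groups
        )
        if not additive.converged:
            raise RuntimeError("additive Laplace fit did not converge")
    except (RuntimeError, np.linalg.LinAlgError) as err:
        warnings.warn(f"Gamma GLMM failed ({err}); falling back to fixed-effects GLM")
        used_fallback = True
        full = _fixed_effects_fallback(formula, data)
        additive = _fixed_effects_fallback(formula.replace("*", "+"), data)

    terms = [t for t in full.design_info.term_names if t != "Intercept"]
    rows = []
    for term in terms:
        source = full if ":" in term else additive
        stat, df, p = _glmm_wald(source, term)
        rows.append({"term": term, "chi2": stat, "df": df, "p": p})
    wald = pd.DataFrame(rows)

    stim_levels = sorted(data["stimulus"].unique())
    k = len(stim_levels)
    con_rows = []
    for tb in sorted(data["time_bin"].unique()):
        grid = pd.DataFrame(
            {"stimulus": stim_levels, "time_c": (tb - 10.5) / 19.0}
        )
        R = _emm_grid(full.design_info, grid)
        for i, s1 in enumerate(stim_levels):
            for s2 in stim_levels[i + 1 :]:
                c = R[i] - R[stim_levels.index(s2)]
                est = float(c @ full.params)
                se = float(np.sqrt(c @ full.cov_params @ c))
                t = est / se if se > 0 else np.nan
                con_rows.append(
                    {
                        "time_bin": tb,
                        "contrast": f"{s1} - {s2}",
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "p_adj": _tukey_p(t, k, max(full.df_resid, 1)),
                    }
                )
    pairwise = pd.DataFrame(con_rows)
    return TemporalModelReport(
        result=full, wald=wald, pairwise=pairwise, used_fallback=used_fallback
    )


def _fixed_effects_fallback(formula: str, data: pd.DataFrame) -> GammaGLMMResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(
            formula, data=data, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
    return GammaGLMMResult(
        params=np.asarray(fit.params),
        param_names=list(fit.params.index),
        cov_params=np.asarray(fit.cov_params()),
        shape=1.0 / float(fit.scale),
        sigma2=0.0,
        loglik=float(fit.llf),
        converged=True,
        n_obs=int(fit.nobs),
        n_groups=0,
        design_info=fit.model.data.design_info,
        random_effects=pd.Series(dtype=float),
    )
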