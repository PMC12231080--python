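"""Statistical models of daily fire spread and the perimeter effect.

* Gaussian linear mixed-effects models of log10 daily area burned and log10
  maximum linear spread on aspen cover (fixed effect) with a random
  intercept per fire, on the full aspen-present patch set and on >5% / >10%
  aspen subsets.
* Per-cover-type contrast models (one mixed model per cover type).
* Top-down covariate selection: drop non-significant first-order terms,
  prune collinear pairs (|r| > 0.3) keeping the individually more predictive
  term (lower single-term AIC), then test aspen x covariate interactions.
* Simple linear models of per-fire aspen FPE on weather/climate means, and a
  penalized smooth of FPE on day-of-year.

Mixed models are fit by maximum likelihood (not REML) so AIC values are
comparable across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

ASPEN_PRESENT_MIN = 0.001  # >= 0.1% aspen defines "aspen present"


@dataclass
class FixedEffect:
    term: str
    estimate: float
    se: float
    p_value: float


@dataclass
class SpreadModelResult:
    response: str
    fixed_effects: list[FixedEffect]
    random_effect_variance: float
    residual_variance: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_patches: int
    n_fires: int
    subset: str = "aspen_present"
    singular: bool = False

    def effect(self, term: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.term == term:
                return fe
        raise KeyError(term)


@dataclass
class SelectionTrace:
    steps: list[tuple[str, str, float]] = field(default_factory=list)

    def record(self, action: str, term: str, metric: float) -> None:
        self.steps.append((action, term, float(metric)))


@dataclass
class SmoothModelResult:
    edf: float
    p_value: float
    r2: float
    alpha: float
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


def prepare_response(patch_table: pd.DataFrame, pixel_size: float = 30.0) -> pd.DataFrame:
    """Add log10 responses and aspen-subset flags to a patch table.

    Both spread metrics are approximately log-normal, so models run on
    log10(area_ha) and log10(max_linear_spread_m). Patches with zero linear
    spread (no-advance days) are floored at half a pixel before the log.
    Subset flags: ``aspen_present`` (>= 0.1% aspen cover), ``gt5`` (> 5%),
    ``gt10`` (> 10%).
    """
    if patch_table.empty:
        raise ValueError("empty patch table")
    df = patch_table.copy()
    floor = pixel_size / 2.0
    df["log10_area_ha"] = np.log10(df["area_ha"])
    df["log10_linear_m"] = np.log10(np.maximum(df["max_linear_spread_m"], floor))
    df["aspen_present"] = df["aspen"] >= ASPEN_PRESENT_MIN
    df["gt5"] = df["aspen"] > 0.05
    df["gt10"] = df["aspen"] > 0.10
    return df


def fit_mixed(table: pd.DataFrame, response: str, fixed_terms: list[str],
              group: str = "fire_id", subset: str = "aspen_present") -> SpreadModelResult:
    """Gaussian linear mixed model with a random intercept per fire.

    Falls back to ordinary least squares (flagged ``singular``) when the
    mixed fit fails or degenerates to zero between-fire variance.
    """
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 fires for a fire-level random effect")
    if len(table) < 10:
        raise ValueError("need at least 10 patches")
    endog = table[response].to_numpy(dtype=float)
    exog = sm.add_constant(table[list(fixed_terms)].astype(float), has_constant="add")
    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = MixedLM(endog, exog.to_numpy(), groups=table[group].to_numpy()).fit(reml=False)
            params = np.asarray(res.fe_params)
            bse = np.asarray(res.bse_fe)
            pvals = np.asarray(res.pvalues)[: len(params)]
            var_re = float(np.asarray(res.cov_re).ravel()[0])
            var_res = float(res.scale)
            aic = float(res.aic)
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        ols = sm.OLS(endog, exog.to_numpy()).fit()
        params = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
        pvals = np.asarray(ols.pvalues)
        var_re, var_res, aic = 0.0, float(ols.scale), float(ols.aic)

    names = list(exog.columns)
    fixed = [FixedEffect(n, float(b), float(s), float(p))
             for n, b, s, p in zip(names, params, bse, pvals)]
    fitted_fixed = exog.to_numpy() @ params
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + var_re + var_res
    return SpreadModelResult(
        response=response,
        fixed_effects=fixed,
        random_effect_variance=var_re,
        residual_variance=var_res,
        aic=aic,
        r2_marginal=var_fixed / denom if denom > 0 else np.nan,
        r2_conditional=(var_fixed + var_re) / denom if denom > 0 else np.nan,
        n_patches=len(table),
        n_fires=int(table[group].nunique()),
        subset=subset,
        singular=singular,
    )


def fit_aspen_models(table: pd.DataFrame, response: str) -> dict[str, SpreadModelResult]:
    """The aspen fixed-effect model on the three nested aspen subsets."""
    out = {}
    for flag in ("aspen_present", "gt5", "gt10"):
        sub = table[table[flag]]
        if sub["fire_id"].nunique() >= 2 and len(sub) >= 10:
            out[flag] = fit_mixed(sub, response, ["aspen"], subset=flag)
    return out


def fit_cover_contrasts(table: pd.DataFrame, cover_types: list[str],
                        response: str) -> tuple[dict[str, SpreadModelResult], list[str]]:
    """One mixed model per cover type, that type's proportion as the fixed
    effect. Types with no variance (or absent) are skipped with a notice."""
    results: dict[str, SpreadModelResult] = {}
    skipped: list[str] = []
    for ct in cover_types:
        if ct not in table.columns or table[ct].nunique() <= 1:
            skipped.append(ct)
            continue
        results[ct] = fit_mixed(table, response, [ct])
    return results, skipped


def select_model(table: pd.DataFrame, response: str, candidate_terms: list[str],
                 alpha: float = 0.05, r_threshold: float = 0.3,
                 focal: str = "aspen") -> tuple[SpreadModelResult, SelectionTrace]:
    """Top-down covariate selection around the focal (aspen) term.

    1. Fit all candidate terms plus the focal term as first-order effects.
    2. Drop candidates with Wald p >= alpha (the focal term is never
       dropped).
    3. Among surviving candidate pairs with Pearson |r| > ``r_threshold``,
       keep the individually more predictive term (lower single-term-model
       AIC), dropping the other; repeat until no correlated pair remains.
    4. Test focal x survivor interactions one at a time, accepting an
       interaction only if it lowers AIC and is significant at ``alpha``;
       repeat until no interaction qualifies.

    If the selected model somehow ends with a higher AIC than the all-terms
    initial model, the initial model is returned instead (selection never
    accepts a worse model than its starting point).
    """
    trace = SelectionTrace()
    candidates = [t for t in candidate_terms if t != focal]
    initial = fit_mixed(table, response, [focal] + candidates)

    survivors = []
    for t in candidates:
        p = initial.effect(t).p_value
        if p >= alpha:
            trace.record("drop_nonsignificant", t, p)
        else:
            survivors.append(t)

    # single-term predictive ability for collinearity tie-breaks
    single_aic = {t: fit_mixed(table, response, [t]).aic for t in survivors}
    while True:
        worst = None
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                r = abs(float(np.corrcoef(table[a], table[b])[0, 1]))
                if r > r_threshold and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        r, a, b = worst
        drop = a if single_aic[a] > single_aic[b] else b
        survivors.remove(drop)
        trace.record("drop_collinear", drop, r)

    work = table.copy()
    terms = [focal] + survivors
    current = fit_mixed(work, response, terms)
    remaining = list(survivors)
    while remaining:
        best = None
        for t in remaining:
            col = f"{focal}:{t}"
            work[col] = work[focal] * work[t]
            cand = fit_mixed(work, response, terms + [col])
            if cand.aic < current.aic and cand.effect(col).p_value < alpha:
                if best is None or cand.aic < best[0].aic:
                    best = (cand, t, col)
        if best is None:
            break
        current, t, col = best
        terms.append(col)
        remaining.remove(t)
        trace.record("add_interaction", col, current.aic)

    if current.aic > initial.aic:
        trace.record("keep_initial", "", initial.aic)
        return initial, trace
    return current, trace


def fit_fpe_covariate_lm(fpe_by_fire: pd.DataFrame, covariates: list[str],
                         fpe_col: str = "fpe") -> pd.DataFrame:
    """Simple linear model of per-fire aspen FPE on each covariate mean.

    Requires at least 10 fires; constant covariates are skipped. Returns one
    row per covariate with slope, SE, p-value, and r-squared.
    """
    df = fpe_by_fire.dropna(subset=[fpe_col])
    if len(df) < 10:
        raise ValueError("need at least 10 fires with defined FPE")
    if float(np.var(df[fpe_col])) < 1e-12:
        raise ValueError("FPE is constant across fires; no model is estimable")
    rows = []
    for cov in covariates:
        if cov not in df.columns or float(np.var(df[cov].astype(float))) < 1e-12:
            continue
        X = sm.add_constant(df[[cov]].astype(float))
        res = sm.OLS(df[fpe_col].astype(float), X).fit()
        rows.append({
            "covariate": cov,
            "slope": float(res.params[cov]),
            "se": float(res.bse[cov]),
            "p_value": float(res.pvalues[cov]),
            "r2": float(res.rsquared),
            "n": int(len(df)),
        })
    return pd.DataFrame(rows)


def fit_fpe_doy_smooth(fpe_values, doy_values, basis_df: int = 10,
                       n_grid: int = 100) -> SmoothModelResult:
    """Penalized univariate smooth of FPE on day-of-year.

    B-spline basis of dimension ``basis_df`` with the penalty weight chosen
    by generalized cross-validation; reports the smooth's effective degrees
    of freedom, an approximate Wald p-value, r-squared, and the fitted curve
    with pointwise 95% bands on a DOY grid. Requires >= 20 fires spanning at
    least 60 days.
    """
    y = np.asarray(list(fpe_values), dtype=float)
    doy = np.asarray(list(doy_values), dtype=float)
    ok = np.isfinite(y) & np.isfinite(doy)
    y, doy = y[ok], doy[ok]
    if y.size < 20:
        raise ValueError("need at least 20 fires for the seasonal smooth")
    if doy.max() - doy.min() < 60:
        raise ValueError("day-of-year range must span at least 60 days")

    # constant term as plain exog so the penalized smooth carries only the
    # seasonal deviation (otherwise a nonzero mean masquerades as signal)
    const = np.ones((y.size, 1))
    bs = BSplines(doy[:, None], df=[basis_df], degree=[3], include_intercept=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = GLMGam(y, exog=const, smoother=bs, alpha=1.0)
        base.fit()
        alpha = float(np.atleast_1d(base.select_penweight(criterion="gcv")[0])[0])
        res = GLMGam(y, exog=const, smoother=bs, alpha=alpha).fit()
        smooth_edf = float(np.sum(res.edf[const.shape[1]:]))
        if smooth_edf < 1e-6:
            # smooth fully penalized away: no seasonal signal
            p_value = 1.0
        else:
            p_value = float(np.squeeze(res.test_significance(0).pvalue))
    edf = smooth_edf
    fitted = np.asarray(res.fittedvalues)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    grid = np.linspace(doy.min(), doy.max(), n_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = res.get_prediction(exog=np.ones((n_grid, 1)),
                                  exog_smooth=grid[:, None])
        ci = pred.conf_int()
    return SmoothModelResult(
        edf=edf, p_value=p_value, r2=r2, alpha=alpha,
        grid=grid, fitted=np.asarray(pred.predicted_mean),
        ci_low=np.asarray(ci[:, 0]), ci_high=np.asarray(ci[:, 1]), n=int(y.size),
    )


def model_summary_frame(results: dict[str, SpreadModelResult]) -> pd.DataFrame:
    """Flatten model results into one row per (model, fixed-effect term)."""
    rows = []
    for key, res in results.items():
        for fe in res.fixed_effects:
            rows.append({
                "model": key,
                "response": res.response,
                "subset": res.subset,
                "term": fe.term,
                "estimate": fe.estimate,
                "se": fe.se,
                "p_value": fe.p_value,
                "aic": res.aic,
                "r2_marginal": res.r2_marginal,
                "r2_conditional": res.r2_conditional,
                "random_effect_variance": res.random_effect_variance,
                "residual_variance": res.residual_variance,
                "n_patches": res.n_patches,
                "n_fires": res.n_fires,
                "singular": res.singular,
            })
    return pd.DataFrame(rows)
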