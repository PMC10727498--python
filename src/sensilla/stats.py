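"""Group comparisons with mixed models and adjusted post-hoc contrasts.

Responses (log firing rates, adaptation series, feeding measures) are
compared across stimuli with Gaussian linear mixed models carrying a
random intercept per animal (electrophysiology) or per colony
(behaviour).  Fixed-effect terms are tested with Wald F statistics using
a residual-degrees-of-freedom approximation (denominator df = n - p);
a model whose interaction term is not significant at 0.05 is refit
additively and the additive fit is reported.  Post-hoc pairwise
contrasts of estimated marginal means are adjusted with Tukey's
studentized-range criterion; many-to-one comparisons against a control
group use Dunnett's multivariate-t test.  Singular random-effect fits
fall back to a fixed-effects OLS model with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA_INTERACTION = 0.05
#: Asterisk convention: *, p<0.05; **, p<0.001; ***, p<0.0001.
STAR_LEVELS = ((1e-4, "***"), (1e-3, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, sym in STAR_LEVELS:
        if p < cut:
            return sym
    return "ns"


@dataclass
class ModelSpec:
    """Declarative description of one comparison."""

    response: str
    fixed: list[str]
    random_intercept: str
    interaction: bool = True
    family: str = "gaussian"


@dataclass
class ComparisonResult:
    anova: pd.DataFrame  # term, F, df1, df2, p
    contrasts: pd.DataFrame  # pair, estimate, se, t, p_adj, stars
    model_used: str  # "interaction" | "additive" | "ols-fallback"
    aic: float
    bic: float
    notes: list[str] = field(default_factory=list)


def _formula(spec: ModelSpec, interaction: bool) -> str:
    terms = [f"C({f})" for f in spec.fixed]
    joiner = " * " if (interaction and len(terms) > 1) else " + "
    return f"{spec.response} ~ {joiner.join(terms)}"


def _fit_mixed(formula: str, data: pd.DataFrame, group: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[group])
        res = model.fit(reml=True)
    singular = not np.all(np.isfinite(res.bse_fe)) or float(res.cov_re.iloc[0, 0]) < 1e-10
    return res, singular


def _fit_ols(formula: str, data: pd.DataFrame):
    return smf.ols(formula, data).fit()


def _wald_anova(res, n_obs: int, mixed: bool) -> pd.DataFrame:
    """Per-term Wald F tests on the fixed effects."""
    di = res.model.data.design_info
    k_fe = res.model.k_fe if mixed else len(res.params)
    n_params = len(res.params)
    rows = []
    df_denom = n_obs - k_fe
    for term, sl in di.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = range(sl.start, sl.stop)
        L = np.zeros((len(list(idx)), n_params))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        w = res.wald_test(L, use_f=True, scalar=False)
        rows.append(
            {
                "term": term.replace("C(", "").replace(")", ""),
                "F": float(np.squeeze(w.statistic)),
                "df1": int(w.df_num),
                "df2": float(w.df_denom) if w.df_denom is not None else df_denom,
                "p": float(np.squeeze(w.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def _emmeans(res, data: pd.DataFrame, factor: str, mixed: bool) -> pd.DataFrame:
    """Estimated marginal means for ``factor``.

    Each level's EMM is the model prediction averaged over a balanced
    reference grid of the other fixed factors.
    """
    di = res.model.data.design_info
    # reference grid: all combinations of the fixed-factor levels
    fixed_names = []
    for name in di.term_names:
        if name == "Intercept" or ":" in name:
            continue
        fixed_names.append(name[2:-1])  # strip C( )
    grids = {f: sorted(data[f].unique()) for f in fixed_names}
    levels = grids[factor]
    others = [f for f in fixed_names if f != factor]
    rows = []
    for lev in levels:
        combos = (
            [dict(zip(others, vals)) for vals in itertools.product(*[grids[o] for o in others])]
            if others
            else [{}]
        )
        X = []
        for combo in combos:
            rec = {factor: lev, **combo}
            Xrow = patsy.build_design_matrices([di], pd.DataFrame([rec]))[0]
            X.append(np.asarray(Xrow)[0])
        Xbar = np.mean(X, axis=0)
        full = np.zeros(len(res.params))
        full[: Xbar.size] = Xbar
        est = float(full @ np.asarray(res.params))
        cov = np.asarray(res.cov_params())
        se = float(np.sqrt(full @ cov @ full))
        rows.append({"level": lev, "emmean": est, "se": se, "_x": full})
    return pd.DataFrame(rows)


def tukey_contrasts(
    res, data: pd.DataFrame, factor: str, mixed: bool, df_denom: float
) -> pd.DataFrame:
    """All pairwise contrasts of ``factor`` EMMs with Tukey adjustment."""
    em = _emmeans(res, data, factor, mixed)
    k = len(em)
    cov = np.asarray(res.cov_params())
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        xi, xj = em["_x"].iloc[i], em["_x"].iloc[j]
        d = xi - xj
        est = float(d @ np.asarray(res.params))
        se = float(np.sqrt(d @ cov @ d))
        if se == 0:
            t = 0.0
            p = 1.0
        else:
            t = est / se
            q = abs(t) * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df_denom))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "contrast": f"{em['level'].iloc[i]} - {em['level'].iloc[j]}",
                "estimate": est,
                "se": se,
                "t": t,
                "p_adj": p,
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows)


def fit_compare(data: pd.DataFrame, spec: ModelSpec) -> ComparisonResult:
    """Fit the declared mixed model and report term tests + contrasts.

    The interaction model is fit first (when declared); a non-significant
    interaction (p >= 0.05) triggers an additive refit which is then
    reported, mirroring standard practice for these designs.
    """
    notes: list[str] = []
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    n = len(data)

    def fit(interaction: bool):
        formula = _formula(spec, interaction)
        res, singular = _fit_mixed(formula, data, spec.random_intercept)
        mixed = True
        if singular:
            notes.append("singular random-effect fit; OLS fallback used")
            log.warning("singular mixed fit for %s; falling back to OLS", formula)
            res = _fit_ols(formula, data)
            mixed = False
        return res, mixed

    use_interaction = spec.interaction and len(spec.fixed) > 1
    res, mixed = fit(use_interaction)
    anova = _wald_anova(res, n, mixed)
    model_used = "interaction" if use_interaction else "additive"
    if use_interaction:
        inter = anova[anova["term"].str.contains(":")]
        if not inter.empty and float(inter["p"].iloc[0]) >= ALPHA_INTERACTION:
            res, mixed = fit(False)
            anova = _wald_anova(res, n, mixed)
            model_used = "additive"
            notes.append("interaction non-significant; additive model reported")
    if not mixed:
        model_used = "ols-fallback"
    k_fe = res.model.k_fe if mixed else len(res.params)
    df_denom = n - k_fe
    contrasts = tukey_contrasts(res, data, spec.fixed[0], mixed, df_denom)
    return ComparisonResult(
        anova=anova,
        contrasts=contrasts,
        model_used=model_used,
        aic=float(res.aic) if res.aic is not None else np.nan,
        bic=float(res.bic) if res.bic is not None else np.nan,
        notes=notes,
    )


def drop_interaction_by_ic(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[bool, dict[str, float]]:
    """Drop the interaction iff both AIC and BIC improve without it."""
    full, fmix = _fit_mixed(_formula(spec, True), data, spec.random_intercept)
    red, rmix = _fit_mixed(_formula(spec, False), data, spec.random_intercept)
    ic = {
        "aic_full": float(full.aic), "bic_full": float(full.bic),
        "aic_reduced": float(red.aic), "bic_reduced": float(red.bic),
    }
    drop = ic["aic_reduced"] < ic["aic_full"] and ic["bic_reduced"] < ic["bic_full"]
    return drop, ic


def dunnett_vs_control(
    data: pd.DataFrame,
    response: str,
    group_col: str,
    control: str,
) -> pd.DataFrame:
    """Many-to-one comparisons against the control group (Dunnett).

    Simultaneous multivariate-t inference over all treatment-vs-control
    contrasts; family-wise error is controlled at the test level.
    """
    groups = sorted(data[group_col].unique())
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    treatments = [g for g in groups if g != control]
    if not treatments:
        raise ValueError("need at least one non-control group")
    ctrl = data.loc[data[group_col] == control, response].dropna().to_numpy()
    samples = [
        data.loc[data[group_col] == g, response].dropna().to_numpy()
        for g in treatments
    ]
    res = sps.dunnett(*samples, control=ctrl)
    rows = []
    for g, est, p in zip(treatments, res.statistic, res.pvalue):
        p = float(p)
        rows.append(
            {
                "contrast": f"{g} - {control}",
                "statistic": float(est),
                "p_adj": p,
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows)


def maybe_log_transform(
    data: pd.DataFrame, response: str, spec: ModelSpec, alpha: float = 0.01
) -> tuple[pd.DataFrame, bool]:
    """log10(x+1)-transform a response whose OLS residuals fail Shapiro.

    Returns the (possibly transformed) data and whether the transform was
    applied; behavioural responses are only transformed when clearly
    non-normal.
    """
    res = _fit_ols(_formula(spec, False), data.dropna(subset=[response]))
    _, p = sps.shapiro(res.resid)
    if p < alpha:
        out = data.copy()
        out[response] = np.log10(out[response] + 1.0)
        return out, True
    return data, False
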