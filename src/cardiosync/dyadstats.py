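"""Dyad-level statistical modelling of synchrony.

Synchrony is a between-dyad outcome, so within-dyad predictors (each member
has their own score: social anxiety, perspective taking, HRV change) enter
the model as the dyad SUM and the dyad ABSDIFF (absolute difference) of the
two members' scores.  The procedure fits a saturated model with both kinds
of terms plus the between-dyad factors, and — if no ABSDIFF term is
significant — refits a trimmed model keeping only the SUMs.  All models
carry a by-dyad random intercept (random slopes configurable, with an
automatic dropping ladder on non-convergence), p-values are FDR-adjusted
within each model's coefficient family, and each model is compared against
a random-intercept-only null.

Factor codings follow the reporting convention in which "old" blocks and
"leader-follower" / "opposite" levels carry the indicator: a negative
novelty coefficient therefore means *higher* synchrony in new blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sp_stats

__all__ = [
    "DyadDesign",
    "FormulaSpec",
    "ModelReport",
    "build_dyad_design",
    "fit_mixed_model",
    "saturated_then_trim",
    "fdr_adjust",
    "lag_group_contrast",
]

#: continuous predictors standardized at design-build time
_CONTINUOUS = ["grasp_diff_ms", "start_diff_ms",
               "sum_social_anxiety", "absdiff_social_anxiety",
               "sum_perspective_taking", "absdiff_perspective_taking",
               "sum_hrv_change", "absdiff_hrv_change"]


@dataclass
class DyadDesign:
    """Model-ready table: one row per dyad-block, standardized predictors."""

    table: pd.DataFrame
    scalers: dict
    sum_terms: list
    absdiff_terms: list
    between_terms: list


@dataclass
class FormulaSpec:
    """Contract for the mixed-model engine."""

    outcome: str
    fixed: list
    group: str = "dyad"
    random_slopes: list = field(default_factory=list)


@dataclass
class ModelReport:
    """Fixed effects with raw and FDR-adjusted p-values, plus diagnostics."""

    params: pd.DataFrame            # name, estimate, ci_low, ci_high, p, p_fdr
    trimmed: bool
    converged: bool
    random_structure: str
    null_comparison: dict           # chi2, df, p
    r2: dict                        # marginal, conditional


def _sum_absdiff(per_subject: pd.DataFrame, value: str, keys: list) -> pd.DataFrame:
    wide = per_subject.pivot_table(index=keys, columns="subject", values=value)
    out = pd.DataFrame({
        f"sum_{value}": wide["s1"] + wide["s2"],
        f"absdiff_{value}": (wide["s1"] - wide["s2"]).abs(),
    })
    return out.reset_index()


def build_dyad_design(study, synchrony_table: pd.DataFrame,
                      hrv: pd.DataFrame | None = None,
                      behavior: pd.DataFrame | None = None,
                      standardize: bool = True) -> DyadDesign:
    """Join synchrony, HRV, behavioral, and questionnaire tables into one
    dyad-block design with SUM/ABSDIFF within-dyad predictors.

    Outcome is the x100 Fisher-Z synchrony (``scaled``).  Baseline blocks are
    excluded.  Continuous predictors are z-standardized (means/SDs stored in
    ``scalers``); factors become 0/1 indicators ``novelty_old``,
    ``block_type_lf``, ``movement_opposite``.
    """
    tab = synchrony_table.loc[~synchrony_table["is_baseline"]].copy()
    tab["outcome"] = tab["scaled"]
    n_before = len(tab)
    tab = tab.dropna(subset=["outcome"])
    if len(tab) < n_before:
        import logging
        logging.getLogger(__name__).warning(
            "dropped %d rows with missing outcome", n_before - len(tab))
    tab["novelty_old"] = (tab["novelty"] == "old").astype(float)
    tab["block_type_lf"] = (tab["block_type"] == "leader_follower").astype(float)
    tab["movement_opposite"] = (tab["movement"] == "opposite").astype(float)

    subjects = study.subjects_table()
    for col in ("social_anxiety", "perspective_taking"):
        sa = _sum_absdiff(subjects, col, ["dyad"])
        tab = tab.merge(sa, on="dyad", how="left")
    if hrv is not None:
        hc = _sum_absdiff(hrv.rename(columns={"change": "hrv_change"}),
                          "hrv_change", ["dyad", "block"])
        tab = tab.merge(hc, on=["dyad", "block"], how="left")
    if behavior is not None:
        tab = tab.merge(behavior, on=["dyad", "block"], how="left")

    scalers = {}
    if standardize:
        for col in _CONTINUOUS:
            if col not in tab.columns:
                continue
            mu, sd = tab[col].mean(), tab[col].std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"constant predictor {col!r} cannot be standardized")
            scalers[col] = (float(mu), float(sd))
            tab[col] = (tab[col] - mu) / sd

    sum_terms = [c for c in tab.columns if c.startswith("sum_")]
    absdiff_terms = [c for c in tab.columns if c.startswith("absdiff_")]
    between = ["block_type_lf", "novelty_old"]
    for c in ("grasp_diff_ms", "start_diff_ms"):
        if c in tab.columns:
            between.append(c)
    return DyadDesign(table=tab, scalers=scalers, sum_terms=sum_terms,
                      absdiff_terms=absdiff_terms, between_terms=between)


def fit_mixed_model(design: DyadDesign | pd.DataFrame, spec: FormulaSpec,
                    reml: bool = True) -> ModelReport:
    """Fit a linear mixed model (REML) with a by-group random intercept and
    the requested random slopes.

    Random slopes that prevent convergence are dropped one at a time (last
    first), down to a random intercept only; the structure actually fit is
    recorded in the report.  The model is compared to an intercept-only null
    by an ML likelihood-ratio test, and Nakagawa marginal/conditional R2 are
    reported.
    """
    tab = design.table if isinstance(design, DyadDesign) else design
    missing = [c for c in spec.fixed + [spec.outcome, spec.group] if c not in tab.columns]
    if missing:
        raise ValueError(f"unknown columns in formula spec: {missing}")
    data = tab.dropna(subset=spec.fixed + [spec.outcome]).copy()
    formula = f"{spec.outcome} ~ " + " + ".join(spec.fixed) if spec.fixed else f"{spec.outcome} ~ 1"

    ladder = [spec.random_slopes[:k] for k in range(len(spec.random_slopes), -1, -1)]
    res = None
    structure = "intercept"
    for slopes in ladder:
        re_formula = "~" + " + ".join(["1"] + slopes)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data[spec.group],
                                    re_formula=re_formula)
                cand = model.fit(reml=reml, method=["lbfgs", "powell"])
            if cand.converged and np.all(np.isfinite(cand.bse_fe)):
                res = cand
                structure = "intercept" if not slopes else "intercept + " + " + ".join(slopes)
                break
        except (np.linalg.LinAlgError, ValueError):
            continue
    converged = res is not None
    if res is None:
        # full fallback: OLS-style fit via random intercept with fixed tiny variance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data[spec.group])
            res = model.fit(reml=reml, method="powell", maxiter=200)
        structure = "intercept (not converged)"

    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    pvals = res.pvalues.loc[fe.index]
    names = [n for n in fe.index if n != "Intercept"]
    family_p = pvals.loc[names].to_numpy()
    p_fdr = fdr_adjust(family_p) if len(names) else np.array([])
    params = pd.DataFrame({
        "name": fe.index,
        "estimate": fe.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": pvals.to_numpy(),
    })
    params["p_fdr"] = params["p"]
    params.loc[params["name"].isin(names), "p_fdr"] = p_fdr

    null_cmp = _null_comparison(data, spec, formula)
    r2 = _nakagawa_r2(res, data, spec)
    return ModelReport(params=params, trimmed=False, converged=converged,
                       random_structure=structure, null_comparison=null_cmp, r2=r2)


def _null_comparison(data: pd.DataFrame, spec: FormulaSpec, formula: str) -> dict:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(formula, data, groups=data[spec.group]).fit(reml=False)
            null = smf.mixedlm(f"{spec.outcome} ~ 1", data,
                               groups=data[spec.group]).fit(reml=False)
        chi2 = 2.0 * (full.llf - null.llf)
        df = len(spec.fixed)
        return {"chi2": float(chi2), "df": df,
                "p": float(sp_stats.chi2.sf(max(chi2, 0.0), df)) if df else np.nan}
    except (np.linalg.LinAlgError, ValueError):
        return {"chi2": np.nan, "df": len(spec.fixed), "p": np.nan}


def _nakagawa_r2(res, data: pd.DataFrame, spec: FormulaSpec) -> dict:
    try:
        fitted_fixed = res.model.exog @ res.fe_params.to_numpy()
        var_f = float(np.var(fitted_fixed))
        var_r = float(np.trace(res.cov_re) if res.cov_re.size else 0.0)
        var_e = float(res.scale)
        tot = var_f + var_r + var_e
        return {"marginal": var_f / tot, "conditional": (var_f + var_r) / tot}
    except Exception:
        return {"marginal": np.nan, "conditional": np.nan}


def saturated_then_trim(design: DyadDesign, between: list | None = None,
                        alpha: float = 0.05,
                        random_slopes: list | None = None,
                        estimation=fit_mixed_model) -> ModelReport:
    """Saturated (SUM + ABSDIFF + between-dyad terms) then trimmed model.

    If every ABSDIFF predictor's raw p-value is >= ``alpha`` in the saturated
    fit, the ABSDIFF terms are removed and the SUM-only trimmed model is
    returned (``trimmed=True``); otherwise the saturated report is returned.
    FDR adjustment is applied within the reported model's coefficients.
    """
    between = design.between_terms if between is None else between
    fixed_sat = between + design.sum_terms + design.absdiff_terms
    spec_sat = FormulaSpec(outcome="outcome", fixed=fixed_sat,
                           random_slopes=random_slopes or [])
    report_sat = estimation(design, spec_sat)
    absdiff_p = report_sat.params.set_index("name").loc[
        [t for t in design.absdiff_terms], "p"]
    if (absdiff_p >= alpha).all():
        spec_trim = FormulaSpec(outcome="outcome", fixed=between + design.sum_terms,
                                random_slopes=random_slopes or [])
        report = estimation(design, spec_trim)
        report.trimmed = True
        return report
    return report_sat


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj p_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, in the original
    order of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def lag_group_contrast(synchrony_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format lag-group table for the Block x LagGroup interaction model.

    One row per dyad-block-laggroup with the mean CCF of that group; feed to
    :func:`fit_mixed_model` with ``block_type * lag_group`` style indicator
    columns as needed.
    """
    needed = ["lag_group_negative", "lag_group_zero", "lag_group_positive"]
    if any(c not in synchrony_table.columns for c in needed):
        raise ValueError("synchrony table lacks lag-group columns")
    long = synchrony_table.melt(
        id_vars=[c for c in ("dyad", "block", "block_type", "leader",
                             "is_baseline") if c in synchrony_table.columns],
        value_vars=needed, var_name="lag_group", value_name="ccf_mean")
    long["lag_group"] = long["lag_group"].str.replace("lag_group_", "", regex=False)
    return long
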