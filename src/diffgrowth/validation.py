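"""Validation of the growth factors against later outcomes.

Two stages mirror the study design: (1) age-8 symptom scales attached to
the growth model as additional indicators regressed on the latent intercept
and slope, with LRT-based selection among both-paths / intercept-only /
slope-only variants; (2) extracted factor scores predicting registry-style
diagnosis case status in logistic regressions with mother-clustered robust
standard errors, reported as per-SD odds ratios.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .growth import (
    GrowthSpec,
    delta_method,
    factor_scores,
    fit_growth,
    lrt,
    _marginal_factor_cov,
)
from .exposures import fdr_adjust, select_variant

SYMPTOM_LABELS = {
    "s_dep": "DEP", "s_anx": "ANX", "s_hyp": "HYP",
    "s_inat": "INAT", "s_cd": "CD", "s_odd": "ODD",
}


def _standardise_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        v = out[c]
        out[c] = (v - v.mean()) / v.std(ddof=1)
    return out


def fit_symptom_paths(
    scored: pd.DataFrame,
    outcome: str = "diff",
    symptoms: tuple = tuple(SYMPTOM_LABELS),
    *,
    covariates: tuple = ("sex", "parity"),
    cluster: str = "mother_id",
    select_alpha: float = 0.05,
    standardise: bool = True,
    joint: bool = False,
):
    """Growth-factor paths to age-8 symptom scales.

    Each symptom is attached to its own growth model (six separate fits) by
    default; ``joint=True`` attaches all six at once (their residuals stay
    mutually uncorrelated in that parameterisation).  Returns
    ``(SymptomPathTable, chosen_variants)``; betas are standardised against
    the marginal factor SD and the (unit) symptom SD.
    """
    data = _standardise_columns(scored, symptoms) if standardise else scored
    sym_groups = [tuple(symptoms)] if joint else [(s,) for s in symptoms]

    rows, chosen_variants = [], {}
    for group in sym_groups:
        base = GrowthSpec(outcome=outcome, covariates=covariates,
                          symptoms=group, cluster=cluster)
        fits = {
            v: fit_growth(data, replace(base, symptom_target=v))
            for v in ("both", "intercept_only", "slope_only")
        }
        chosen, _tests = select_variant(fits, alpha=select_alpha)
        fit = fits[chosen]
        layout = fit._layout
        pars = fit.params()
        for s in group:
            chosen_variants[s] = chosen
            row_idx = layout.k_wave + list(group).index(s)
            sd_s = np.sqrt(
                pars["theta"][row_idx]
                + pars["Lam"][row_idx] @ _marginal_factor_cov(
                    fit, fit.estimates.to_numpy()
                ) @ pars["Lam"][row_idx]
            )
            r2 = 1.0 - pars["theta"][row_idx] / sd_s**2
            for fac in ("I", "S"):
                name = f"lam_{s}_{fac}"
                if name not in fit.names:
                    rows.append({"symptom": s, "outcome": SYMPTOM_LABELS.get(s, s),
                                 "factor": fac, "beta": 0.0, "se": np.nan,
                                 "p": np.nan, "fixed_zero": True, "r2": r2,
                                 "variant": chosen})
                    continue
                f_idx = fit.spec.factor_names.index(fac)

                def std_path(nat, f_idx=f_idx, row_idx=row_idx):
                    alpha_, Gamma_, kappa_, Psi_, Lam_, nu_, theta_, *_ = (
                        layout.unpack(nat, natural=True)
                    )
                    P = _marginal_factor_cov(fit, nat)
                    sd_fac = np.sqrt(P[f_idx, f_idx])
                    sd_sym = np.sqrt(
                        theta_[row_idx] + Lam_[row_idx, :2] @ P @ Lam_[row_idx, :2]
                    )
                    return Lam_[row_idx, f_idx] * sd_fac / sd_sym

                beta, se = delta_method(fit, std_path)
                z = beta / se
                rows.append({"symptom": s, "outcome": SYMPTOM_LABELS.get(s, s),
                             "factor": fac, "beta": beta, "se": se,
                             "p": 2 * stats.norm.sf(abs(z)), "fixed_zero": False,
                             "r2": r2, "variant": chosen})
    tab = pd.DataFrame(rows)
    tab["ci_low"] = tab.beta - 1.96 * tab.se
    tab["ci_high"] = tab.beta + 1.96 * tab.se
    tested = ~tab.fixed_zero
    q = np.full(len(tab), np.nan)
    q[tested.to_numpy()] = fdr_adjust(tab.loc[tested, "p"].to_numpy())
    tab["q"] = q
    return tab, chosen_variants


class SeparationWarning(UserWarning):
    pass


def _cluster_logit(y, X, groups):
    """Logit fit with cluster-robust covariance; penalised fallback on
    separation or non-convergence (flagged, not silent)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        if not np.isfinite(res.bse).all() or (np.abs(res.params) > 15).any():
            raise ValueError("unstable estimates")
    except Exception:
        flagged = True
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
    return res, flagged


def fit_diagnosis_logits(
    scores: pd.DataFrame,
    cases: pd.DataFrame,
    covariate_data: pd.DataFrame | None = None,
    *,
    covariates: tuple = ("sex", "parity"),
    cluster: str = "mother_id",
    factor_cols: tuple = ("eta_I", "eta_S"),
) -> pd.DataFrame:
    """Per-SD odds ratios of diagnosis case status on factor scores.

    One logistic model per diagnosis category, predictors re-standardised to
    SD 1 internally, mother-clustered robust SEs, Wald CIs exponentiated
    from the log-odds scale.  Categories with zero cases are skipped with a
    diagnostic row; separation triggers a penalised fallback and a flag.
    """
    df = scores.merge(cases, on="child_id")
    if covariate_data is not None:
        cov_cols = ["child_id", *covariates]
        if cluster not in df.columns and cluster in covariate_data.columns:
            cov_cols.append(cluster)
        df = df.merge(covariate_data[cov_cols], on="child_id")
    use_covs = [c for c in covariates if c in df.columns]
    df = df.dropna(subset=[*factor_cols, *use_covs])
    for c in factor_cols:
        df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
    groups = df[cluster] if cluster in df.columns else df["child_id"]

    categories = [c for c in cases.columns if c != "child_id"]
    rows = []
    for cat in categories:
        y = df[cat].astype(float)
        if y.sum() == 0:
            rows.append({"category": cat, "factor": None, "or": np.nan,
                         "skipped": True, "note": "zero cases"})
            continue
        X = sm.add_constant(df[[*factor_cols, *use_covs]].astype(float))
        res, flagged = _cluster_logit(y, X, groups)
        se = getattr(res, "bse", pd.Series(np.nan, index=res.params.index))
        for fac_col, fac in zip(factor_cols, ("I", "S")):
            b = res.params[fac_col]
            s = se[fac_col]
            rows.append({
                "category": cat, "factor": fac, "or": np.exp(b),
                "ci_low": np.exp(b - 1.96 * s), "ci_high": np.exp(b + 1.96 * s),
                "p": 2 * stats.norm.sf(abs(b / s)) if np.isfinite(s) else np.nan,
                "log_or": b, "se_log_or": s, "n_cases": int(y.sum()),
                "skipped": False, "penalised": flagged, "note": "",
            })
    return pd.DataFrame(rows)


def validate_outcomes(scored, cases, *, outcome="diff", cluster="mother_id",
                      covariates=("sex", "parity"), growth_fit=None):
    """Convenience wrapper: symptom paths + factor-score diagnosis ORs."""
    sym_tab, variants = fit_symptom_paths(
        scored, outcome, covariates=covariates, cluster=cluster
    )
    if growth_fit is None:
        growth_fit = fit_growth(
            scored, GrowthSpec(outcome=outcome, covariates=covariates,
                               cluster=cluster)
        )
    fs = factor_scores(growth_fit, scored)
    fs = fs.merge(scored[["child_id", cluster]], on="child_id")
    diag_tab = fit_diagnosis_logits(fs, cases, scored, covariates=covariates,
                                    cluster=cluster)
    return sym_tab, diag_tab, variants
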