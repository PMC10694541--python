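"""Early-life-exposure effects on the growth factors, with model-variant
selection and false-discovery-rate control.

The exposures enter the growth model jointly (mutually adjusted).  Three
structural variants are fitted -- exposures influencing both factors, the
intercept only, or the slope only -- and likelihood-ratio tests against the
full variant pick the best-fitting one (falling back to BIC when both
reductions survive).  p-values from the selected model's cluster-robust
Wald tests are BH-adjusted within the outcome's family of exposure x factor
tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .growth import GrowthSpec, fit_growth, lrt, standardised_beta


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


_VARIANTS = ("both", "intercept_only", "slope_only")


def select_variant(fits: dict, *, alpha: float = 0.05):
    """LRT-based choice among both / intercept-only / slope-only fits.

    Keep the full model when dropping either set of paths significantly
    hurts fit; when exactly one reduction is tenable take it; when both are,
    prefer the lower BIC (the two reduced models are not nested in each
    other).
    """
    test_i = lrt(fits["both"], fits["intercept_only"])  # tests slope paths
    test_s = lrt(fits["both"], fits["slope_only"])      # tests intercept paths
    i_ok = test_i.p >= alpha
    s_ok = test_s.p >= alpha
    if not i_ok and not s_ok:
        chosen = "both"
    elif i_ok and not s_ok:
        chosen = "intercept_only"
    elif s_ok and not i_ok:
        chosen = "slope_only"
    else:
        chosen = min(("intercept_only", "slope_only"), key=lambda v: fits[v].bic())
    return chosen, {"intercept_only": test_i, "slope_only": test_s}


def effect_table(fit, exposures, *, outcome_label: str, variant: str,
                 fdr_level: float = 0.05) -> pd.DataFrame:
    """Standardised exposure -> factor estimates with BH q-values.

    The FDR family is all exposure x free-factor tests within this outcome's
    model, matching a per-outcome correction.
    """
    rows = []
    for x in exposures:
        for fac in ("I", "S"):
            name = f"b_{x}_{fac}"
            if name not in fit.names:
                continue
            beta, se_b = standardised_beta(fit, x, fac)
            rows.append({"exposure": x, "factor": fac, "beta": beta, "se": se_b})
    tab = pd.DataFrame(rows)
    from scipy import stats

    tab["ci_low"] = tab.beta - 1.96 * tab.se
    tab["ci_high"] = tab.beta + 1.96 * tab.se
    tab["p"] = 2 * stats.norm.sf(np.abs(tab.beta / tab.se))
    tab["q"] = fdr_adjust(tab["p"].to_numpy())
    tab["significant_fdr"] = tab["q"] <= fdr_level
    tab["outcome"] = outcome_label
    tab["variant"] = variant
    return tab


def fit_exposure_models(
    scored: pd.DataFrame,
    exposures: tuple,
    outcome: str = "diff",
    *,
    covariates: tuple = ("sex", "parity"),
    weights: str | None = None,
    cluster: str = "mother_id",
    select_alpha: float = 0.05,
    fdr_level: float = 0.05,
    marginal: bool = False,
):
    """Fit the exposure growth model in its three variants and tabulate.

    ``marginal=True`` fits one exposure at a time instead of jointly (a
    sensitivity mode).  Returns ``(EffectTable, fits, selection_tests)``.
    """
    exposures = tuple(exposures)
    X = scored[list(exposures)]
    rank = np.linalg.matrix_rank(X.cov().to_numpy())
    if rank < len(exposures):
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().sort_values(ascending=False).head(4)
        raise ValueError(
            "exposure block is rank-deficient; most collinear columns: "
            + ", ".join(f"{c} (|r|max={v:.3f})" for c, v in worst.items())
        )

    if marginal:
        tabs = []
        for x in exposures:
            tab, fits, _ = fit_exposure_models(
                scored, (x,), outcome, covariates=covariates, weights=weights,
                cluster=cluster, select_alpha=select_alpha, fdr_level=fdr_level,
            )
            tabs.append(tab)
        tab = pd.concat(tabs, ignore_index=True)
        tab["q"] = fdr_adjust(tab["p"].to_numpy())
        tab["significant_fdr"] = tab["q"] <= fdr_level
        return tab, None, None

    base = GrowthSpec(
        outcome=outcome, covariates=covariates, predictors=exposures,
        weights=weights, cluster=cluster,
    )
    fits = {v: fit_growth(scored, replace(base, predictor_target=v))
            for v in _VARIANTS}
    chosen, tests = select_variant(fits, alpha=select_alpha)
    tab = effect_table(fits[chosen], exposures, outcome_label=outcome,
                       variant=chosen, fdr_level=fdr_level)
    return tab, fits, tests
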