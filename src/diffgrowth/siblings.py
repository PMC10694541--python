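"""Sibling-subsample analysis: selection weighting, within/between exposure
decomposition, and family-confounding-adjusted effect estimation.

Families contribute to the sibling analyses only if two children
participate.  Because selection into that subsample depends on observed
variables, sibling-only models carry stabilised inverse-probability
weights from a logistic regression of sibling status on all other study
variables.  Each exposure is then split into a family mean and a child
deviation (a within/between, or Mundlak, decomposition): the deviation
coefficient is free of confounding that is shared within the nuclear
family, and its attenuation relative to the unadjusted coefficient is the
design's confounding signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth import GrowthSpec, fit_growth, standardised_beta
from .exposures import fdr_adjust

from dataclasses import dataclass


@dataclass
class WeightVector:
    weights: pd.Series            # indexed by child_id, sibling children only
    coefficients: pd.Series
    truncated: int
    truncation_threshold: float
    min_propensity: float
    n_low_overlap: int


def estimate_sibling_weights(
    scored: pd.DataFrame,
    *,
    sibling_col: str = "is_sibling",
    exposures: tuple = (),
    covariates: tuple = ("sex", "parity"),
    wave_cols: tuple = ("diff_1", "diff_2", "diff_3"),
    truncate_pct: float = 99.0,
    overlap_floor: float = 1e-3,
) -> WeightVector:
    """Stabilised IPW making the sibling subsample resemble the full cohort.

    P(sibling | x) is estimated on the full sample from exposures,
    covariates and wave scores (missing wave scores enter as zero plus a
    missingness indicator, so every child is usable); sibling children get
    w = P(S=1) / P-hat(S=1 | x), truncated at the ``truncate_pct``-th
    percentile and renormalised to mean 1.
    """
    feats = pd.DataFrame(index=scored.index)
    for c in (*exposures, *covariates):
        feats[c] = scored[c].astype(float)
    for c in wave_cols:
        miss = scored[c].isna()
        feats[c] = scored[c].fillna(0.0)
        if miss.any():
            feats[f"{c}_miss"] = miss.astype(float)
    X = sm.add_constant(feats)
    y = scored[sibling_col].astype(float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    phat = np.asarray(res.predict(X))

    sib = scored[sibling_col].astype(bool).to_numpy()
    p_marg = y.mean()
    p_sib = phat[sib]
    n_low = int((p_sib < overlap_floor).sum())
    if n_low:
        warnings.warn(
            f"{n_low} sibling children have estimated selection probability "
            f"below {overlap_floor}: weights are unstable (non-overlap)"
        )
    w = p_marg / np.maximum(p_sib, overlap_floor)
    cap = np.percentile(w, truncate_pct)
    truncated = int((w > cap).sum())
    w = np.minimum(w, cap)
    w = w / w.mean()
    return WeightVector(
        weights=pd.Series(w, index=scored.loc[sib, "child_id"].to_numpy(),
                          name="ipw"),
        coefficients=res.params,
        truncated=truncated,
        truncation_threshold=float(cap),
        min_propensity=float(p_sib.min()),
        n_low_overlap=n_low,
    )


def decompose_within_between(
    data: pd.DataFrame, exposures: tuple, *, family_col: str = "mother_id"
):
    """Split each exposure into family mean and child deviation.

    Only families with >= 2 children are retained (singletons carry no
    within-family information).  Returns ``(decomposed, shares)`` where
    ``shares`` is the within-family variance share per exposure; shares
    below 1% are flagged "education-like" (near-invariant within families,
    so adjusted estimates rest on very few discordant pairs).
    """
    sizes = data.groupby(family_col)["child_id"].transform("size")
    df = data.loc[sizes >= 2].copy()
    shares = {}
    for x in exposures:
        fam_mean = df.groupby(family_col)[x].transform("mean")
        df[f"{x}_between"] = fam_mean
        df[f"{x}_within"] = df[x] - fam_mean
        total = df[x].var(ddof=1)
        shares[x] = float(df[f"{x}_within"].var(ddof=1) / total) if total > 0 else 0.0
    shares = pd.Series(shares, name="within_share")
    shares.attrs["education_like"] = list(shares.index[shares < 0.01])
    return df, shares


def fit_sibling_models(
    scored: pd.DataFrame,
    exposures: tuple,
    *,
    outcome: str = "diff",
    covariates: tuple = ("sex", "parity"),
    cluster: str = "mother_id",
    weights: WeightVector | None = None,
    fdr_level: float = 0.05,
    noise_floor_se: float = 2.0,
):
    """Unadjusted vs family-confounding-adjusted exposure effects.

    Both models are fitted on the sibling subsample with IPW weights and
    mother-clustered SEs.  The unadjusted model regresses the growth
    factors on the raw exposures; the adjusted model on (family mean, child
    deviation), taking the deviation coefficient as the within-family
    effect.  Returns ``(pair_table, fits)``; the attenuation ratio is
    flagged undefined when the unadjusted estimate is within
    ``noise_floor_se`` SEs of zero.
    """
    exposures = tuple(exposures)
    decomposed, shares = decompose_within_between(scored, exposures,
                                                  family_col=cluster)
    if weights is not None:
        decomposed = decomposed.merge(
            weights.weights.rename("ipw"), left_on="child_id", right_index=True,
            how="left",
        )
        decomposed["ipw"] = decomposed["ipw"].fillna(1.0)
        wcol = "ipw"
    else:
        wcol = None

    spec_unadj = GrowthSpec(
        outcome=outcome, covariates=covariates, predictors=exposures,
        weights=wcol, cluster=cluster,
    )
    fit_unadj = fit_growth(decomposed, spec_unadj)
    adj_preds = tuple(f"{x}_within" for x in exposures) + tuple(
        f"{x}_between" for x in exposures
    )
    spec_adj = GrowthSpec(
        outcome=outcome, covariates=covariates, predictors=adj_preds,
        weights=wcol, cluster=cluster,
    )
    fit_adj = fit_growth(decomposed, spec_adj)

    from scipy import stats

    rows = []
    for x in exposures:
        sd_raw = decomposed[x].std(ddof=1)
        for fac in ("I", "S"):
            # both effects per SD of the *raw* exposure, so attenuation of
            # the within-family estimate is read off a common scale
            b_u, se_u = standardised_beta(fit_unadj, x, fac, scale_sd=sd_raw)
            b_a, se_a = standardised_beta(fit_adj, f"{x}_within", fac,
                                          scale_sd=sd_raw)
            unreliable = shares[x] < 0.01
            atten = (
                b_a / b_u if abs(b_u) > noise_floor_se * se_u else np.nan
            )
            rows.append({
                "exposure": x, "factor": fac,
                "beta_unadjusted": b_u, "se_unadjusted": se_u,
                "beta_adjusted": b_a, "se_adjusted": se_a,
                "ci_low_unadjusted": b_u - 1.96 * se_u,
                "ci_high_unadjusted": b_u + 1.96 * se_u,
                "ci_low_adjusted": b_a - 1.96 * se_a,
                "ci_high_adjusted": b_a + 1.96 * se_a,
                "p_unadjusted": 2 * stats.norm.sf(abs(b_u / se_u)),
                "p_adjusted": 2 * stats.norm.sf(abs(b_a / se_a)),
                "attenuation": atten,
                "within_share": shares[x],
                "adjusted_unreliable": bool(unreliable),
            })
    tab = pd.DataFrame(rows)
    tab["q_adjusted"] = fdr_adjust(tab["p_adjusted"].to_numpy())
    tab["q_unadjusted"] = fdr_adjust(tab["p_unadjusted"].to_numpy())
    return tab, {"unadjusted": fit_unadj, "adjusted": fit_adj,
                 "within_shares": shares}
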