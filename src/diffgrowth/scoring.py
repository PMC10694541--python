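"""Construction of standardised, differentiation and total scores, and
registry case classification.

Differentiation at each wave is the difference between the standardised
behavioural and emotional subscale scores (positive = relatively more
behavioural problems); the total score is their sum.  Because both are
linear combinations of the same pair of z-scores, the two are orthogonal by
construction on the standardisation population.

A child is a diagnostic "case" for a category if, between their 8th
birthday and the end of follow-up, they have at least two recorded contacts
in primary care, at least two in secondary care, or at least one in each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DIAG_CATEGORIES, FOLLOWUP_END

WAVES = (1, 2, 3)


class ScoringError(ValueError):
    pass


def standardise_wave(values: pd.Series | np.ndarray, *, ddof: int = 1):
    """z-score a wave's subscale values over the non-missing children.

    Returns ``(z, mean, sd)``.  Missing in, missing out.  The constants are
    computed over all children observed at that wave (not complete cases
    across waves), consistent with the full-information estimation
    philosophy downstream.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 2:
        raise ScoringError("need at least 2 non-missing values to standardise")
    mean = obs.mean()
    sd = obs.std(ddof=ddof)
    if sd <= 0 or not np.isfinite(sd):
        raise ScoringError("zero or undefined variance: cannot standardise")
    z = (v - mean) / sd
    if isinstance(values, pd.Series):
        z = pd.Series(z, index=values.index, name=values.name)
    return z, float(mean), float(sd)


def compute_diff_total(z_beh, z_emo):
    """diff = z_beh - z_emo, tot = z_beh + z_emo; missing if either missing."""
    return z_beh - z_emo, z_beh + z_emo


def score_cohort(cohort: pd.DataFrame, *, ddof: int = 1):
    """Attach z_beh_w, z_emo_w, diff_w, tot_w columns for each wave.

    Returns ``(scored, constants)`` where ``constants`` maps
    ``(subscale, wave) -> (mean, sd)`` for reuse on new data.
    """
    scored = cohort.copy()
    constants = {}
    for w in WAVES:
        for sub in ("beh", "emo"):
            z, mean, sd = standardise_wave(cohort[f"{sub}_{w}"], ddof=ddof)
            scored[f"z_{sub}_{w}"] = z
            constants[(sub, w)] = (mean, sd)
        scored[f"diff_{w}"], scored[f"tot_{w}"] = compute_diff_total(
            scored[f"z_beh_{w}"], scored[f"z_emo_{w}"]
        )
    return scored, constants


def diff_total_correlations(scored: pd.DataFrame,
                            complete: str = "wave") -> pd.Series:
    """Complete-case Pearson r between diff_w and tot_w per wave.

    ``complete="wave"`` correlates over the children observed at that wave
    (the standardisation population, where orthogonality is exact up to
    numerical precision); ``complete="all"`` restricts to children observed
    at all three waves, where the correlation is nonzero only through the
    subpopulation's sampling noise.
    """
    if complete == "all":
        base = scored.dropna(subset=[f"diff_{w}" for w in WAVES])
    elif complete == "wave":
        base = scored
    else:
        raise ScoringError(f"unknown complete-case rule {complete!r}")
    out = {}
    for w in WAVES:
        sub = base[[f"diff_{w}", f"tot_{w}"]].dropna()
        out[w] = sub[f"diff_{w}"].corr(sub[f"tot_{w}"])
    return pd.Series(out, name="corr_diff_tot")


def classify_cases(
    contacts: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    followup_end: pd.Timestamp = FOLLOWUP_END,
    count_same_day_once: bool = False,
) -> pd.DataFrame:
    """Apply the two-contact case rule per diagnosis category.

    Only contacts inside ``[8th birthday, followup_end]`` count.  Two
    same-day contacts count as two by default (the rule counts diagnoses,
    with no de-duplication clause); ``count_same_day_once`` collapses them.
    """
    known = set(cohort["child_id"])
    unknown = set(contacts["child_id"]) - known
    if unknown:
        raise ScoringError(
            f"contacts reference {len(unknown)} unknown child_id(s), e.g. "
            f"{sorted(unknown)[:3]}"
        )
    bad_cat = set(contacts["category"]) - set(DIAG_CATEGORIES)
    if bad_cat:
        raise ScoringError(f"unknown diagnosis categories {sorted(bad_cat)}")

    birth = cohort.set_index("child_id")["birth_date"]
    c = contacts.copy()
    c["date"] = pd.to_datetime(c["date"])
    start = pd.to_datetime(birth.loc[c["child_id"]].to_numpy()) + pd.DateOffset(years=8)
    in_window = (c["date"].to_numpy() >= start.to_numpy()) & (
        c["date"] <= followup_end
    ).to_numpy()
    c = c.loc[in_window]
    if count_same_day_once:
        c = c.drop_duplicates(["child_id", "category", "care_level", "date"])

    counts = (
        c.groupby(["child_id", "category", "care_level"], observed=True)
        .size()
        .unstack("care_level", fill_value=0)
    )
    for lvl in ("primary", "secondary"):
        if lvl not in counts:
            counts[lvl] = 0
    is_case = (
        (counts["primary"] >= 2)
        | (counts["secondary"] >= 2)
        | ((counts["primary"] >= 1) & (counts["secondary"] >= 1))
    )
    flags = is_case.unstack("category", fill_value=False)

    out = pd.DataFrame(index=pd.Index(cohort["child_id"], name="child_id"))
    for cat in DIAG_CATEGORIES:
        col = flags[cat] if cat in flags else pd.Series(False, index=flags.index)
        out[cat] = col.reindex(out.index, fill_value=False).astype(bool)
    return out.reset_index()
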