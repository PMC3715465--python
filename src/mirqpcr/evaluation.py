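"""Marker and panel characterization beyond the case/control cohort.

Covers: negativity rates in disease-control cohorts (OA, SLE), ACPA
subgroup sensitivity with Fisher's exact test, Pearson correlations with
clinical covariates, age-stratified group comparison, and treatment
association via multivariable logistic regression.

Call convention throughout: a sample is positive when its score reaches the
cutoff (>=, direction-adjusted), so "true negative" means strictly below.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .panel_model import fit_logistic, lr_test_drop_one


def positive_calls(scores, cutoff: float, positive_direction: str = "high_is_positive"):
    scores = np.asarray(scores, dtype=float)
    if positive_direction == "high_is_positive":
        return scores >= cutoff
    if positive_direction == "low_is_positive":
        return scores <= cutoff
    raise ValidationError(f"unknown direction {positive_direction!r}")


def control_group_negativity(
    scores, cutoff: float, positive_direction: str = "high_is_positive"
) -> tuple[float, int, int]:
    """Fraction of a control cohort classified negative.

    Returns ``(fraction_negative, n_negative, n_total)``.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValidationError("cohort is empty")
    calls = positive_calls(scores, cutoff, positive_direction)
    n_neg = int((~calls).sum())
    return n_neg / len(scores), n_neg, len(scores)


def subgroup_sensitivity(
    scores, cutoff: float, subgroup, positive_direction: str = "high_is_positive"
) -> dict[str, float]:
    """Sensitivity within and outside a case subgroup, with Fisher exact p.

    ``subgroup`` is boolean per case sample (e.g. ACPA-positive).  The p
    value is the two-sided Fisher exact test on the 2x2 table of positive
    call x subgroup membership.
    """
    subgroup = np.asarray(subgroup, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if subgroup.all() or not subgroup.any():
        raise ValidationError("both subgroups must be non-empty")
    calls = positive_calls(scores, cutoff, positive_direction)
    a = int(calls[subgroup].sum())
    b = int((~calls[subgroup]).sum())
    c = int(calls[~subgroup].sum())
    d = int((~calls[~subgroup]).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "sensitivity_in": a / (a + b),
        "sensitivity_out": c / (c + d),
        "n_in": a + b,
        "n_out": c + d,
        "fisher_p": float(p),
    }


def clinical_correlations(
    values: pd.DataFrame, covariates: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson r (two-sided t-based p, n-2 df) for every marker x covariate.

    Pairwise-complete observations; pairs with fewer than ``min_n``
    observations or zero variance are reported with NaN r and an
    explanatory note rather than dropped.
    """
    rows = []
    for marker in values.columns:
        for covariate in covariates.columns:
            x = values[marker].to_numpy(dtype=float)
            y = covariates[covariate].reindex(values.index).to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            n = int(mask.sum())
            row = {"marker": marker, "covariate": covariate, "n": n}
            if n < min_n:
                row.update(r=np.nan, p=np.nan, note="insufficient n")
            elif x[mask].std() == 0 or y[mask].std() == 0:
                row.update(r=np.nan, p=np.nan, note="zero variance")
            else:
                r, p = stats.pearsonr(x[mask], y[mask])
                row.update(r=float(r), p=float(p), note="")
            rows.append(row)
    return pd.DataFrame(rows)


def age_stratified_compare(
    values: pd.DataFrame,
    groups: pd.Series,
    age: pd.Series,
    *,
    case: str = "RA",
    control: str = "HC",
    decade_start: int = 30,
    decade_stop: int = 80,
    min_n: int = 2,
) -> pd.DataFrame:
    """Per-decade case/control comparison of each marker.

    Decade bins are [30, 40), [40, 50), ... on age in years.  Decades where
    either group has fewer than ``min_n`` samples are flagged
    ``insufficient_n`` and reported without a p value, never silently
    dropped.
    """
    labels = groups.reindex(values.index)
    age = age.reindex(values.index).astype(float)
    rows = []
    edges = list(range(decade_start, decade_stop + 10, 10))
    for marker in values.columns:
        for low, high in zip(edges[:-1], edges[1:]):
            in_decade = (age >= low) & (age < high)
            rows.append(
                _decade_row(values[marker], labels, in_decade, marker, low, high,
                            case, control, min_n)
            )
    return pd.DataFrame(rows)


def _decade_row(col, labels, in_decade, marker, low, high, case, control, min_n):
    case_vals = col[in_decade & (labels == case)].to_numpy(dtype=float)
    control_vals = col[in_decade & (labels == control)].to_numpy(dtype=float)
    case_vals = case_vals[np.isfinite(case_vals)]
    control_vals = control_vals[np.isfinite(control_vals)]
    row = {
        "marker": marker,
        "decade": f"[{low},{high})",
        f"n_{case.lower()}": len(case_vals),
        f"n_{control.lower()}": len(control_vals),
        f"mean_{case.lower()}": case_vals.mean() if len(case_vals) else np.nan,
        f"sd_{case.lower()}": case_vals.std(ddof=1) if len(case_vals) > 1 else np.nan,
        f"mean_{control.lower()}": control_vals.mean() if len(control_vals) else np.nan,
        f"sd_{control.lower()}": control_vals.std(ddof=1) if len(control_vals) > 1 else np.nan,
    }
    if len(case_vals) >= min_n and len(control_vals) >= min_n:
        t, p = stats.ttest_ind(case_vals, control_vals, equal_var=True)
        row.update(t_p=float(p), flag="")
    else:
        row.update(t_p=np.nan, flag="insufficient_n")
    return row


def treatment_association(
    calls, drug_flags: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Multivariable logistic regression of test positivity on drug flags.

    One row per flag with odds ratio and drop-one likelihood-ratio p.
    Perfect separation surfaces as the fit error of the underlying logistic
    module.
    """
    calls = np.asarray(calls, dtype=float)
    features = drug_flags.astype(float)
    if len(features) <= features.shape[1] + 1:
        raise ValidationError("n must exceed number of flags + 1")
    model = fit_logistic(features, calls)
    lr = lr_test_drop_one(model, features, calls).set_index("feature")
    rows = []
    for flag, coef in zip(model.feature_ids, model.coefficients):
        rows.append(
            {
                "flag": flag,
                "odds_ratio": float(np.exp(coef)),
                "lr_chisq": lr.loc[flag, "lr_chisq"],
                "lr_p": lr.loc[flag, "lr_p"],
                "significant": bool(lr.loc[flag, "lr_p"] < alpha),
            }
        )
    return pd.DataFrame(rows)
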