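"""Single-marker statistics: Student's t, ROC/AUC, and cutoff selection.

The ROC is built on the observed score values as thresholds (plus a +inf
sentinel) with "positive if score >= threshold" classification after
direction adjustment; AUC is the trapezoidal area, identical to the
Mann-Whitney probability that a random case outscores a random control with
ties counted half.

Cutoff selection is specificity-biased: with J(t) = sensitivity(t) +
specificity(t) and M = max J, the selected threshold maximises specificity
among thresholds whose J is within ``window`` (default 0.03) of M; ties go
to the highest threshold.  Window 0 reduces to the Youden argmax with a
specificity tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def two_group_ttest(values, labels) -> tuple[float, float]:
    """Equal-variance two-sided Student's t.

    ``labels`` is boolean (True = case).  Degenerate pooled variance is
    handled by convention: equal means -> (0, 1); unequal means -> p = 0
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    a, b = values[labels], values[~labels]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test requires n >= 2 per group")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class RocResult:
    """ROC coordinates, AUC, and (after selection) the decision cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_direction: str = "high_is_positive"
    cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None

    def coordinates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(scores, labels, positive_direction: str = "high_is_positive") -> RocResult:
    """Empirical ROC over the observed score values.

    ``labels`` boolean, True = case.  For ``low_is_positive`` markers the
    scores are negated internally and thresholds reported on the original
    scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValidationError("ROC requires both classes present")
    if positive_direction not in ("high_is_positive", "low_is_positive"):
        raise ValidationError(f"unknown direction {positive_direction!r}")
    flip = positive_direction == "low_is_positive"
    s = -scores if flip else scores

    n_case = int(labels.sum())
    n_control = int((~labels).sum())
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        calls = s >= t
        sens[i] = calls[labels].sum() / n_case
        spec[i] = (~calls[~labels]).sum() / n_control
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    out_thresholds = -thresholds if flip else thresholds
    return RocResult(
        thresholds=out_thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_direction=positive_direction,
    )


def select_cutoff(roc: RocResult, window: float = 0.03) -> RocResult:
    """Specificity-biased cutoff within ``window`` of the maximal J."""
    j = roc.sensitivity + roc.specificity
    m = j.max()
    eligible = np.flatnonzero(j >= m - window)
    best_spec = roc.specificity[eligible].max()
    candidates = eligible[roc.specificity[eligible] == best_spec]
    # highest threshold = most conservative call for a high-is-positive marker
    finite_pref = candidates[np.isfinite(roc.thresholds[candidates])]
    pool = finite_pref if len(finite_pref) else candidates
    if roc.positive_direction == "low_is_positive":
        pick = pool[np.argmin(roc.thresholds[pool])]
    else:
        pick = pool[np.argmax(roc.thresholds[pool])]
    return replace(
        roc,
        cutoff=float(roc.thresholds[pick]),
        sens_at_cutoff=float(roc.sensitivity[pick]),
        spec_at_cutoff=float(roc.specificity[pick]),
    )


def marker_report(
    values: pd.DataFrame,
    groups: pd.Series,
    markers: list[str] | None = None,
    *,
    case: str = "RA",
    control: str = "HC",
    window: float = 0.03,
) -> pd.DataFrame:
    """Per-marker summary table: group means +/- SD, t p, AUC, cutoff, sens, spec.

    ``values`` is a samples x assays matrix (typically concentrations in
    pM).  Rows are ordered by AUC descending.
    """
    markers = list(markers) if markers is not None else list(values.columns)
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise ValidationError(f"markers absent from matrix: {missing}")
    labels_full = groups.reindex(values.index)
    keep = labels_full.isin([case, control]).to_numpy()
    rows = []
    for marker in markers:
        col = values[marker].to_numpy(dtype=float)[keep]
        labels = (labels_full[keep] == case).to_numpy()
        finite = np.isfinite(col)
        col, lab = col[finite], labels[finite]
        t, p = two_group_ttest(col, lab)
        roc = select_cutoff(roc_curve(col, lab), window=window)
        rows.append(
            {
                "marker": marker,
                f"mean_{case.lower()}": col[lab].mean(),
                f"sd_{case.lower()}": col[lab].std(ddof=1),
                f"mean_{control.lower()}": col[~lab].mean(),
                f"sd_{control.lower()}": col[~lab].std(ddof=1),
                "t_p": p,
                "auc": roc.auc,
                "cutoff": roc.cutoff,
                "sensitivity": roc.sens_at_cutoff,
                "specificity": roc.spec_at_cutoff,
            }
        )
    report = pd.DataFrame(rows).sort_values(
        ["auc", "marker"], ascending=[False, True], kind="mergesort"
    )
    return report.reset_index(drop=True)
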