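"""Multivariable logistic panel modelling and the ePRAM probability score.

The panel model is a plain maximum-likelihood binomial logistic regression
of case status on marker concentrations (pM, untransformed by default).
Per-feature importance is the drop-one likelihood-ratio test
``LR = 2 (ll_full - ll_reduced)`` against chi-square with 1 df; the panel is
the set of features with LR p below alpha, refit on its own.

The score is reported in the field's sign convention: with eta the fitted
log-odds of case status, define ``x = -eta`` so that the published form
``exp(-x) / (1 + exp(-x))`` equals the fitted probability of disease.  A
sample is called positive when the score reaches the cutoff (default 0.50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import SeparationError, SingularDesignError, ValidationError

@dataclass
class EpramModel:
    """Fitted logistic panel producing the ePRAM probability."""

    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    log_likelihood: float
    cutoff: float = 0.50
    lr_chisq: dict[str, float] = field(default_factory=dict)
    lr_p: dict[str, float] = field(default_factory=dict)
    selected: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_ids):
            raise ValidationError("one coefficient per feature required")
        if not (0.0 < self.cutoff < 1.0):
            raise ValidationError("cutoff must be in (0, 1)")

    def linear_predictor(self, features: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_ids if f not in features.columns]
        if missing:
            raise ValidationError(f"missing features: {missing}")
        x = features[self.feature_ids].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValidationError("missing feature values; no implicit imputation")
        return pd.Series(
            self.intercept + x @ self.coefficients, index=features.index, name="eta"
        )


def _design(features: pd.DataFrame) -> np.ndarray:
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("features contain missing values")
    if (x.std(axis=0) == 0).any():
        bad = [c for c, s in zip(features.columns, x.std(axis=0)) if s == 0]
        raise SingularDesignError(f"constant feature(s): {bad}")
    design = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    return design


def fit_logistic(features: pd.DataFrame, labels, cutoff: float = 0.50) -> EpramModel:
    """Maximum-likelihood logistic fit of case status on features.

    Raises :class:`SeparationError` when the classes are perfectly
    separable (diverging coefficients) and :class:`SingularDesignError` for
    rank-deficient designs (e.g. a duplicated feature).
    """
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValidationError("labels must be binary (case=1, control=0)")
    if len(features) != len(labels):
        raise ValidationError("features and labels length mismatch")
    if len(features) <= features.shape[1] + 1:
        raise ValidationError("need n > k + 1 observations")
    design = _design(features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(labels, design).fit(disp=False, maxiter=100)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SeparationError(
                "perfect separation or ill-conditioned fit; remove the "
                "offending feature or add samples"
            ) from exc
    params = np.asarray(result.params, dtype=float)
    # (quasi-)separation: every fitted probability saturates at 0/1, or the
    # likelihood climb never converged (coefficients drifting to infinity)
    fitted = 1.0 / (1.0 + np.exp(-(design @ params)))
    saturated = np.minimum(fitted, 1.0 - fitted).max() < 1e-6
    if saturated or not result.mle_retvals.get("converged", True):
        raise SeparationError(
            "perfectly separable classes: coefficients diverge; remove the "
            "offending feature or add samples"
        )
    return EpramModel(
        feature_ids=list(features.columns),
        coefficients=params[1:],
        intercept=float(params[0]),
        log_likelihood=float(result.llf),
        cutoff=cutoff,
    )


def lr_test_drop_one(
    model: EpramModel, features: pd.DataFrame, labels
) -> pd.DataFrame:
    """Drop-one likelihood-ratio test per feature of the fitted model.

    Returns a table (feature, lr_chisq, lr_p); the model's ``lr_chisq`` /
    ``lr_p`` dicts are filled in place.  A reduced-model fit failure is
    reported in the table, never silently dropped.
    """
    labels = np.asarray(labels, dtype=float)
    rows = []
    for feature in model.feature_ids:
        kept = [f for f in model.feature_ids if f != feature]
        try:
            if kept:
                reduced = fit_logistic(features[kept], labels, cutoff=model.cutoff)
                ll_reduced = reduced.log_likelihood
            else:
                p1 = labels.mean()
                ll_reduced = float(
                    labels.sum() * np.log(p1) + (1 - labels).sum() * np.log(1 - p1)
                )
        except (SeparationError, SingularDesignError, ValidationError) as exc:
            rows.append(
                {"feature": feature, "lr_chisq": np.nan, "lr_p": np.nan,
                 "note": f"reduced fit failed: {exc}"}
            )
            continue
        lr = max(0.0, 2.0 * (model.log_likelihood - ll_reduced))
        p = float(stats.chi2.sf(lr, df=1))
        model.lr_chisq[feature] = lr
        model.lr_p[feature] = p
        rows.append({"feature": feature, "lr_chisq": lr, "lr_p": p, "note": ""})
    return pd.DataFrame(rows)


def select_panel(
    features: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    cutoff: float = 0.50,
) -> tuple[EpramModel, EpramModel]:
    """Keep features with drop-one LR p < alpha; refit on the kept set.

    Returns ``(full_model, panel_model)``.  The full model carries the LR
    statistics and per-feature ``selected`` flags; the panel model is the
    refit on the selected features (intercept-only with a warning when the
    selection is empty).  Features left out are probed one at a time for
    whether adding them back would significantly improve the panel; the
    result is stored in the full model's ``selected`` audit via the
    returned frame of :func:`addition_check`.
    """
    full = fit_logistic(features, labels, cutoff=cutoff)
    lr_test_drop_one(full, features, labels)
    kept = [f for f in full.feature_ids if full.lr_p.get(f, np.nan) < alpha]
    full.selected = {f: f in kept for f in full.feature_ids}
    if not kept:
        warnings.warn("no feature passed the LR screen; intercept-only panel",
                      stacklevel=2)
        labels_arr = np.asarray(labels, dtype=float)
        p1 = labels_arr.mean()
        ll = float(
            labels_arr.sum() * np.log(p1) + (1 - labels_arr).sum() * np.log(1 - p1)
        )
        panel = EpramModel(
            feature_ids=[], coefficients=np.empty(0),
            intercept=float(np.log(p1 / (1 - p1))), log_likelihood=ll, cutoff=cutoff,
        )
        return full, panel
    panel = fit_logistic(features[kept], labels, cutoff=cutoff)
    panel.selected = {f: True for f in kept}
    return full, panel


def addition_check(
    panel: EpramModel, features: pd.DataFrame, labels, alpha: float = 0.05
) -> pd.DataFrame:
    """Does adding any excluded feature significantly improve the panel?"""
    labels = np.asarray(labels, dtype=float)
    rows = []
    for feature in features.columns:
        if feature in panel.feature_ids:
            continue
        augmented = fit_logistic(
            features[[*panel.feature_ids, feature]], labels, cutoff=panel.cutoff
        )
        lr = max(0.0, 2.0 * (augmented.log_likelihood - panel.log_likelihood))
        p = float(stats.chi2.sf(lr, df=1))
        rows.append(
            {"feature": feature, "lr_chisq": lr, "lr_p": p, "improves": p < alpha}
        )
    return pd.DataFrame(rows)


def epram_score(model: EpramModel, features: pd.DataFrame) -> pd.Series:
    """ePRAM probability per sample: exp(-x)/(1+exp(-x)) with x = -eta."""
    eta = model.linear_predictor(features)
    x = -eta
    return pd.Series(
        1.0 / (1.0 + np.exp(x)), index=features.index, name="epram"
    )


def epram_call(model: EpramModel, features: pd.DataFrame) -> pd.Series:
    """Positive call iff ePRAM >= cutoff."""
    return (epram_score(model, features) >= model.cutoff).rename("call")


def serialize_model(model: EpramModel) -> str:
    """Flat key-value text serialization for bit-for-bit reproducible scores."""
    lines = [
        f"n_features\t{len(model.feature_ids)}",
        f"intercept\t{float(model.intercept)!r}",
        f"cutoff\t{float(model.cutoff)!r}",
        f"log_likelihood\t{float(model.log_likelihood)!r}",
    ]
    for fid, coef in zip(model.feature_ids, model.coefficients):
        lines.append(f"coef\t{fid}\t{float(coef)!r}")
    for fid in model.feature_ids:
        if fid in model.lr_chisq:
            lines.append(
                f"lr\t{fid}\t{float(model.lr_chisq[fid])!r}\t{float(model.lr_p[fid])!r}"
            )
    return "\n".join(lines) + "\n"


def deserialize_model(text: str) -> EpramModel:
    intercept = cutoff = ll = None
    features: list[str] = []
    coefs: list[float] = []
    lr_chisq: dict[str, float] = {}
    lr_p: dict[str, float] = {}
    for line in text.strip().splitlines():
        parts = line.split("\t")
        key = parts[0]
        if key == "intercept":
            intercept = float(parts[1])
        elif key == "cutoff":
            cutoff = float(parts[1])
        elif key == "log_likelihood":
            ll = float(parts[1])
        elif key == "coef":
            features.append(parts[1])
            coefs.append(float(parts[2]))
        elif key == "lr":
            lr_chisq[parts[1]] = float(parts[2])
            lr_p[parts[1]] = float(parts[3])
    if intercept is None or cutoff is None or ll is None:
        raise ValidationError("incomplete model serialization")
    return EpramModel(
        feature_ids=features,
        coefficients=np.asarray(coefs),
        intercept=intercept,
        log_likelihood=ll,
        cutoff=cutoff,
        lr_chisq=lr_chisq,
        lr_p=lr_p,
    )
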