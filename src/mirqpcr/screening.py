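"""Phase-1 array screening and phase-2 confirmation of candidate miRNAs.

Phase 1 screens the small array cohort on -dCt values.  An assay becomes a
candidate if it satisfies any of:

``FOLD4``
    two-sided fold change >= 4 (or <= 1/4) between case and control means;
``CASE_ONLY``
    detected in at least half the case samples and in no control sample;
``P05``
    equal-variance Student's t on -dCt, p < 0.05;

plus the codified manual-inspection rules (on by default):

``MANUAL_P10``
    0.05 <= p < 0.1;
``MANUAL_CT30_FOLD2``
    overall mean raw Ct < 30 with fold >= 2 (or <= 1/2);
``MANUAL_OUTLIER``
    leave-one-out fold crosses the 4-fold bar for some omitted sample while
    the full-data fold does not.

Every assay gets an audit record carrying all satisfied criteria; phase 2
re-tests the merged candidate panel in a larger cohort and delisting removes
quality-failed assays while keeping them in the audit table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import two_group_ttest
from .errors import ValidationError
from .normalization import NormalizedMatrix, fold_change
from .qpcr_io import CtMatrix

CRITERIA_PRIORITY = (
    "FOLD4",
    "CASE_ONLY",
    "P05",
    "MANUAL_P10",
    "MANUAL_CT30_FOLD2",
    "MANUAL_OUTLIER",
)


@dataclass
class ScreeningConfig:
    fold_threshold: float = 4.0
    alpha: float = 0.05
    manual_rules: bool = True
    manual_p_low: float = 0.05
    manual_p_high: float = 0.1
    manual_max_ct: float = 30.0
    manual_fold_threshold: float = 2.0
    loo_fold_threshold: float = 4.0
    min_case_fraction: float = 0.5


@dataclass
class CandidateRecord:
    """Audit record for one assay in the screening pipeline."""

    assay_id: str
    criteria: set[str] = field(default_factory=set)
    fold: float = np.nan
    p_value: float = np.nan
    mean_ct_overall: float = np.nan
    loo_max_fold: float = np.nan
    phase2_p: float | None = None
    phase2_direction: str | None = None
    delisted_reason: list[str] = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return bool(self.criteria)


def _split_groups(
    index: Sequence[str], groups: pd.Series, case: str, control: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = groups.reindex(index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValidationError(f"group label missing for samples: {missing}")
    return (labels == case).to_numpy(), (labels == control).to_numpy()


def detect_case_only(
    ct: CtMatrix,
    groups: pd.Series,
    case: str = "RA",
    control: str = "HC",
    min_case_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Assays detected only in cases (and, symmetrically, only in controls).

    "Detected" means a valid amplification; an assay is case-only when valid
    in at least ``min_case_fraction`` of case samples and in zero controls.
    """
    is_case, is_control = _split_groups(ct.sample_ids, groups, case, control)
    valid = ct.valid.to_numpy()
    case_frac = valid[is_case].mean(axis=0)
    control_frac = valid[is_control].mean(axis=0)
    case_only = [
        a
        for a, cf, hf in zip(ct.assay_ids, case_frac, control_frac)
        if cf >= min_case_fraction and hf == 0.0
    ]
    control_only = [
        a
        for a, cf, hf in zip(ct.assay_ids, case_frac, control_frac)
        if hf >= min_case_fraction and cf == 0.0
    ]
    return case_only, control_only


def _two_sided_fold_hit(fold: float, threshold: float) -> bool:
    return np.isfinite(fold) and (fold >= threshold or fold <= 1.0 / threshold)


def phase1_select(
    norm: NormalizedMatrix,
    ct: CtMatrix,
    groups: pd.Series,
    config: ScreeningConfig | None = None,
    case: str = "RA",
    control: str = "HC",
) -> list[CandidateRecord]:
    """Screen every assay of the array phase; returns one record per assay."""
    config = config or ScreeningConfig()
    is_case, is_control = _split_groups(norm.sample_ids, groups, case, control)
    case_only, _ = detect_case_only(
        ct.subset_assays(norm.assay_ids), groups, case, control, config.min_case_fraction
    )
    case_only_set = set(case_only)

    n_case, n_control = int(is_case.sum()), int(is_control.sum())
    t_possible = n_case >= 2 and n_control >= 2
    if not t_possible:
        warnings.warn(
            "group size < 2: t-based criteria (P05, MANUAL_P10) skipped",
            stacklevel=2,
        )

    records = []
    masked_ct = ct.masked()
    for assay in norm.assay_ids:
        col = norm.values[assay].to_numpy(dtype=float)
        case_vals = col[is_case]
        control_vals = col[is_control]
        case_vals = case_vals[np.isfinite(case_vals)]
        control_vals = control_vals[np.isfinite(control_vals)]

        record = CandidateRecord(assay_id=assay)
        record.mean_ct_overall = float(masked_ct[assay].mean())

        if len(case_vals) and len(control_vals):
            record.fold = fold_change(case_vals.mean(), control_vals.mean())
            record.loo_max_fold = _loo_max_fold(case_vals, control_vals)
        if t_possible and len(case_vals) >= 2 and len(control_vals) >= 2:
            _, record.p_value = two_group_ttest(
                np.concatenate([case_vals, control_vals]),
                np.r_[np.ones(len(case_vals), bool), np.zeros(len(control_vals), bool)],
            )

        if _two_sided_fold_hit(record.fold, config.fold_threshold):
            record.criteria.add("FOLD4")
        if assay in case_only_set:
            record.criteria.add("CASE_ONLY")
        if np.isfinite(record.p_value) and record.p_value < config.alpha:
            record.criteria.add("P05")
        if config.manual_rules:
            if (
                np.isfinite(record.p_value)
                and config.manual_p_low <= record.p_value < config.manual_p_high
            ):
                record.criteria.add("MANUAL_P10")
            if (
                np.isfinite(record.mean_ct_overall)
                and record.mean_ct_overall < config.manual_max_ct
                and _two_sided_fold_hit(record.fold, config.manual_fold_threshold)
            ):
                record.criteria.add("MANUAL_CT30_FOLD2")
            if (
                np.isfinite(record.loo_max_fold)
                and not _two_sided_fold_hit(record.fold, config.loo_fold_threshold)
                and record.loo_max_fold >= config.loo_fold_threshold
            ):
                record.criteria.add("MANUAL_OUTLIER")
        records.append(record)
    return records


def _loo_max_fold(case_vals: np.ndarray, control_vals: np.ndarray) -> float:
    """Max two-sided fold over all single-sample omissions."""
    best = 0.0
    for vals, other, case_side in (
        (case_vals, control_vals, True),
        (control_vals, case_vals, False),
    ):
        if len(vals) < 2:
            continue
        total = vals.sum()
        for i in range(len(vals)):
            mean_loo = (total - vals[i]) / (len(vals) - 1)
            if case_side:
                fc = fold_change(mean_loo, other.mean())
            else:
                fc = fold_change(other.mean(), mean_loo)
            best = max(best, fc, 1.0 / fc)
    return best


def sort_candidates(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Deterministic order: criterion priority, then p ascending, then id."""

    def key(r: CandidateRecord):
        best = min(
            (CRITERIA_PRIORITY.index(c) for c in r.criteria),
            default=len(CRITERIA_PRIORITY),
        )
        p = r.p_value if np.isfinite(r.p_value) else np.inf
        return (best, p, r.assay_id)

    return sorted(records, key=key)


def merge_candidates(
    phase1: Sequence[CandidateRecord] | Sequence[str],
    manual_additions: Sequence[str] = (),
    exclusions: Sequence[str] = (),
) -> list[str]:
    """Union of phase-1 selections and manual additions minus exclusions.

    Accepts either audit records (only selected ones contribute) or bare
    assay id lists.  De-duplicates while preserving first-seen order of the
    sorted phase-1 records followed by the manual additions.
    """
    if phase1 and isinstance(phase1[0], CandidateRecord):
        selected = [r.assay_id for r in sort_candidates(phase1) if r.selected]
    else:
        selected = [str(a) for a in phase1]
    panel: list[str] = []
    for assay in [*selected, *manual_additions]:
        if assay not in panel:
            panel.append(assay)
    for assay in exclusions:
        if assay in panel:
            panel.remove(assay)
        else:
            warnings.warn(f"exclusion of absent assay {assay!r}", stacklevel=2)
    return panel


def phase2_confirm(
    values: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    case: str = "RA",
    control: str = "HC",
    records: Sequence[CandidateRecord] | None = None,
) -> tuple[list[CandidateRecord], list[str]]:
    """Student's t per assay in the confirmation cohort.

    ``values`` is a samples x assays matrix (-dCt or concentrations).
    Returns updated records (phase2_p, direction filled) and the confirmed
    assay list (p < alpha).
    """
    is_case, is_control = _split_groups(values.index, groups, case, control)
    if is_case.sum() < 2 or is_control.sum() < 2:
        raise ValidationError("phase 2 requires n >= 2 per group")
    by_assay = {r.assay_id: r for r in records} if records else {}
    out_records = []
    confirmed = []
    for assay in values.columns:
        col = values[assay].to_numpy(dtype=float)
        case_vals = col[is_case]
        control_vals = col[is_control]
        case_vals = case_vals[np.isfinite(case_vals)]
        control_vals = control_vals[np.isfinite(control_vals)]
        _, p = two_group_ttest(
            np.concatenate([case_vals, control_vals]),
            np.r_[np.ones(len(case_vals), bool), np.zeros(len(control_vals), bool)],
        )
        record = by_assay.get(assay, CandidateRecord(assay_id=assay))
        record = replace(
            record,
            criteria=set(record.criteria),
            delisted_reason=list(record.delisted_reason),
            phase2_p=float(p),
            phase2_direction="up" if case_vals.mean() > control_vals.mean() else "down",
        )
        out_records.append(record)
        if p < alpha:
            confirmed.append(assay)
    return out_records, confirmed


def delist_assays(
    records: Sequence[CandidateRecord],
    qc_flags: Mapping[str, str],
    *,
    active: Sequence[str] | None = None,
) -> tuple[list[CandidateRecord], list[str]]:
    """Remove QC-flagged assays from the active panel, keeping the audit row.

    ``qc_flags`` maps assay id to a reason (``high_ct`` | ``poor_curve`` |
    ``unspecific_primer``).  Reasons accumulate without duplication.
    """
    out_records = []
    for record in records:
        record = replace(
            record,
            criteria=set(record.criteria),
            delisted_reason=list(record.delisted_reason),
        )
        reason = qc_flags.get(record.assay_id)
        if reason is not None and reason not in record.delisted_reason:
            record.delisted_reason.append(reason)
        out_records.append(record)
    pool = list(active) if active is not None else [r.assay_id for r in records]
    remaining = [a for a in pool if a not in qc_flags]
    return out_records, remaining


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Audit table, one row per assay tested."""
    rows = []
    for r in records:
        rows.append(
            {
                "assay": r.assay_id,
                "criteria": ";".join(
                    c for c in CRITERIA_PRIORITY if c in r.criteria
                ),
                "fold": r.fold,
                "p": r.p_value,
                "mean_ct": r.mean_ct_overall,
                "loo_max_fold": r.loo_max_fold,
                "phase2_p": r.phase2_p,
                "delisted_reason": ";".join(r.delisted_reason),
            }
        )
    return pd.DataFrame(rows)
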