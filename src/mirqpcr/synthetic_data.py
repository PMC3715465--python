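"""Synthetic qPCR cohorts with planted truths for every pipeline stage.

The generator emulates the structure of a plasma-miRNA biomarker study:

* per-subject true log2 abundance with a cohort-specific shift, Gaussian
  noise on the Ct scale (the standard qPCR assumption);
* hard censoring at a detection-limit Ct (undetermined cells);
* a spike-in assay with small recovery noise and endogenous normalizer
  candidates with zero planted group shift;
* per-assay standard-curve dilution series (slope near -3.32 cycles per
  decade, i.e. efficiency ~1);
* clinical covariates with planted Pearson correlations realised through a
  Gaussian copula on the latent marker noise (exact on the log scale);
* disease-control cohorts (OA, SLE) with attenuated shifts.

Everything is driven by a single :class:`CohortConfig`; identical config and
seed regenerate identical cohorts, and every planted effect is returned in a
truth record so recovery tests never guess.

Under this model a single marker with Ct shift ``delta`` and between-subject
SD ``sigma`` has binormal ROC area ``Phi(delta / (sigma * sqrt(2)))``, which
is how the default effect sizes are calibrated (see
:func:`calibrate_to_paper_defaults`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .qpcr_io import CtMatrix, DilutionSeries, SampleAnnotation

SPIKE_ASSAY = "cel-miR-39"

#: validated biomarker panel of the modelled study, strongest first
DEFAULT_MARKER_AUCS = {
    "miR-125a-5p": 0.92,
    "miR-24": 0.85,
    "miR-26a": 0.74,
    "miR-28-5p": 0.70,
    "miR-28-3p": 0.68,
    "miR-30c": 0.66,
    "miR-30e-3p": 0.64,
    "miR-126-3p": 0.62,
}

DEFAULT_BASELINE_CT = {
    "miR-24": 19.0,
    "miR-26a": 20.0,
    "miR-125a-5p": 24.0,
    "miR-28-5p": 25.0,
    "miR-28-3p": 26.0,
    "miR-30c": 23.0,
    "miR-30e-3p": 27.0,
    "miR-126-3p": 24.0,
}

EPRAM_FEATURES = ("miR-24", "miR-30a-5p", "miR-125a-5p")


def shift_for_auc(auc: float, sd_ct: float) -> float:
    """Ct shift producing a given binormal AUC at between-subject SD sd_ct."""
    return float(stats.norm.ppf(auc) * sd_ct * np.sqrt(2.0))


def expected_auc(shift_ct: float, sd_ct: float) -> float:
    """Binormal AUC for a planted Ct shift: Phi(delta / (sigma sqrt 2))."""
    return float(stats.norm.cdf(shift_ct / (sd_ct * np.sqrt(2.0))))


@dataclass
class AssaySpec:
    """One planted assay: baseline Ct, noise, per-cohort shift, censoring.

    ``shifts`` maps cohort label to the Ct *decrease* relative to baseline
    (positive = more abundant in that cohort).  Ct above
    ``detection_limit_ct`` is censored to undetermined.
    """

    assay_id: str
    baseline_ct: float
    sd_ct: float
    shifts: dict[str, float] = field(default_factory=dict)
    detection_limit_ct: float = 40.0
    role: str = "marker"  # marker | normalizer | null | spike

    def __post_init__(self) -> None:
        if self.sd_ct <= 0:
            raise ValidationError(f"{self.assay_id}: sd_ct must be positive")
        if not all(np.isfinite(v) for v in self.shifts.values()):
            raise ValidationError(f"{self.assay_id}: shifts must be finite")


@dataclass
class CorrelationSpec:
    """Planted Pearson correlation between a marker's log2 concentration and
    a clinical covariate, within one cohort."""

    marker: str
    covariate: str
    r: float
    group: str = "RA"


@dataclass
class CohortConfig:
    """Full specification of a synthetic validation cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"RA": 102, "HC": 104, "OA": 24, "SLE": 11}
    )
    assays: list[AssaySpec] = field(default_factory=list)
    spike_in_sd: float = 0.5
    spike_baseline_ct: float = 20.0
    acpa_positive_rate: float = 0.85
    hc_acpa_rate: float = 0.01
    correlations: list[CorrelationSpec] = field(default_factory=list)
    age_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RA": (63.6, 12.3),
            "HC": (42.9, 12.3),
            "OA": (68.0, 9.0),
            "SLE": (38.0, 12.0),
        }
    )
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "RA": 10 / 102,
            "HC": 39 / 104,
            "OA": 0.25,
            "SLE": 0.1,
        }
    )
    drug_rates: dict[str, float] = field(
        default_factory=lambda: {
            "dmards": 0.882,
            "mtx": 0.60,
            "steroid": 0.372,
            "biologics": 0.157,
            "nsaids": 0.50,
        }
    )
    curve_slope: float = -3.3219
    curve_intercept: float = 38.0
    curve_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_in_sd <= 0:
            raise ValidationError("spike_in_sd must be positive")
        if not (0.0 <= self.acpa_positive_rate <= 1.0):
            raise ValidationError("acpa_positive_rate must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated data plus the planted-truth record."""

    ct: CtMatrix
    annotations: list[SampleAnnotation]
    groups: pd.Series
    dilution_series: dict[str, DilutionSeries]
    truth: dict


def calibrate_to_paper_defaults(seed: int = 0) -> CohortConfig:
    """The shipped default validation-cohort configuration.

    Marker effect sizes are set through the binormal formula from target
    single-marker AUCs chosen so the published ordering (miR-125a-5p
    strongest, then miR-24, then miR-26a) is stable across seeds at
    n = 102/104; between-subject SD is 2 Ct for every marker.  The
    normalizer miR-30a-5p has no planted shift and raw-Ct SD 1.12
    (miR-301a-5p: 1.36); the spike-in SD is 0.5 cycles.  OA and SLE carry
    attenuated per-marker shifts calibrated to the published true-negative
    rates.  The planted age correlation of miR-125a-5p is r = -0.25 within
    the RA cohort.
    """
    sd = 2.0
    assays = []
    for marker, auc in DEFAULT_MARKER_AUCS.items():
        delta = shift_for_auc(auc, sd)
        if marker == "miR-24":
            oa, sle = 0.32 * delta, 0.05 * delta
        elif marker == "miR-125a-5p":
            oa, sle = 0.25 * delta, 0.49 * delta
        else:
            oa, sle = 0.3 * delta, 0.3 * delta
        assays.append(
            AssaySpec(
                assay_id=marker,
                baseline_ct=DEFAULT_BASELINE_CT[marker],
                sd_ct=sd,
                shifts={"RA": delta, "OA": oa, "SLE": sle},
                role="marker",
            )
        )
    assays.append(
        AssaySpec("miR-30a-5p", baseline_ct=22.0, sd_ct=1.12, role="normalizer")
    )
    assays.append(
        AssaySpec("miR-301a-5p", baseline_ct=26.0, sd_ct=1.36, role="normalizer")
    )
    correlations = [
        CorrelationSpec("miR-125a-5p", "age", -0.25, group="RA"),
        CorrelationSpec("miR-24", "das28_crp", 0.35, group="RA"),
        CorrelationSpec("miR-24", "crp_mg_l", 0.30, group="RA"),
    ]
    return CohortConfig(assays=assays, correlations=correlations, seed=seed)


def _covariate_noise(rng, z_marker: np.ndarray | None, r: float) -> np.ndarray:
    """Latent standard normal correlated with a marker's log2 concentration.

    The marker's log2 concentration is ``-sd * z`` plus constants, so a
    target correlation r with the covariate requires loading ``-r`` on z.
    """
    n = len(z_marker)
    w = rng.standard_normal(n)
    if z_marker is None or r == 0.0:
        return w
    a = -r
    return a * z_marker + np.sqrt(1.0 - a * a) * w


def generate_validation_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the validation-phase cohort defined by ``config``."""
    config = config or calibrate_to_paper_defaults()
    rng = np.random.default_rng(config.seed)

    sample_ids: list[str] = []
    group_labels: list[str] = []
    for group in ("RA", "HC", "OA", "SLE"):
        n = config.n_per_group.get(group, 0)
        sample_ids.extend(f"{group}-{i + 1:03d}" for i in range(n))
        group_labels.extend([group] * n)
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    n_total = len(sample_ids)

    assay_ids = [spec.assay_id for spec in config.assays] + [SPIKE_ASSAY]
    z = rng.standard_normal((n_total, len(config.assays)))
    ct_values = np.empty((n_total, len(assay_ids)))
    group_arr = np.asarray(group_labels)
    for j, spec in enumerate(config.assays):
        shift = np.array([spec.shifts.get(g, 0.0) for g in group_arr])
        ct = spec.baseline_ct - shift + spec.sd_ct * z[:, j]
        ct[ct > spec.detection_limit_ct] = np.nan  # hard detection censoring
        ct_values[:, j] = np.clip(ct, 1.0, None)
    ct_values[:, -1] = config.spike_baseline_ct + config.spike_in_sd * rng.standard_normal(
        n_total
    )

    ct_frame = pd.DataFrame(ct_values, index=sample_ids, columns=assay_ids)
    ct = CtMatrix(ct_frame, ~ct_frame.isna(), phase_tag="validation")

    z_by_marker = {
        spec.assay_id: z[:, j] for j, spec in enumerate(config.assays)
    }
    annotations = _generate_annotations(config, rng, sample_ids, group_arr, z_by_marker)

    dilution_series = _generate_dilution_series(config, rng, assay_ids)

    truth = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "assays": {
            spec.assay_id: {
                "baseline_ct": spec.baseline_ct,
                "sd_ct": spec.sd_ct,
                "shifts": dict(spec.shifts),
                "role": spec.role,
                "expected_auc_ra_vs_hc": expected_auc(
                    spec.shifts.get("RA", 0.0), spec.sd_ct
                ),
            }
            for spec in config.assays
        },
        "spike_in_sd": config.spike_in_sd,
        "correlations": [
            {"marker": c.marker, "covariate": c.covariate, "r": c.r, "group": c.group}
            for c in config.correlations
        ],
        "acpa_positive_rate": config.acpa_positive_rate,
    }
    return SyntheticCohort(
        ct=ct,
        annotations=annotations,
        groups=groups,
        dilution_series=dilution_series,
        truth=truth,
    )


def _generate_annotations(config, rng, sample_ids, group_arr, z_by_marker):
    corr_by_cov = {(c.group, c.covariate): c for c in config.correlations}

    def latent(group_mask, covariate, group):
        spec = corr_by_cov.get((group, covariate))
        n = int(group_mask.sum())
        if spec is None or spec.marker not in z_by_marker:
            return rng.standard_normal(n)
        return _covariate_noise(rng, z_by_marker[spec.marker][group_mask], spec.r)

    annotations: list[SampleAnnotation] = []
    for group in ("RA", "HC", "OA", "SLE"):
        mask = group_arr == group
        n = int(mask.sum())
        if n == 0:
            continue
        mean_age, sd_age = config.age_model[group]
        age = np.clip(mean_age + sd_age * latent(mask, "age", group), 18.0, 100.0)
        male = rng.random(n) < config.male_fraction.get(group, 0.3)
        if group == "RA":
            acpa = rng.random(n) < config.acpa_positive_rate
        elif group == "HC":
            acpa = rng.random(n) < config.hc_acpa_rate
        else:
            acpa = np.full(n, False)
        covs = {"age": age}
        flags: dict[str, np.ndarray] = {}
        if group == "RA":
            covs["das28_crp"] = np.clip(
                3.42 + 1.07 * latent(mask, "das28_crp", group), 0.3, None
            )
            covs["crp_mg_l"] = np.clip(
                11.6 + 17.3 * latent(mask, "crp_mg_l", group), 0.0, None
            )
            covs["esr_mm"] = np.clip(
                29.7 + 26.4 * rng.standard_normal(n), 1.0, None
            )
            covs["mmp3_ng_ml"] = np.clip(
                164.0 + 140.0 * rng.standard_normal(n), 5.0, None
            )
            covs["vas_mm"] = np.clip(46.0 + 24.3 * rng.standard_normal(n), 0.0, 100.0)
            covs["sjc"] = rng.poisson(3.6, n).astype(float)
            covs["tjc"] = rng.poisson(2.4, n).astype(float)
            flags = {
                name: rng.random(n) < rate for name, rate in config.drug_rates.items()
            }
        ids = np.asarray(sample_ids, dtype=object)[mask]
        for i, sid in enumerate(ids):
            annotations.append(
                SampleAnnotation(
                    sample_id=str(sid),
                    group=group,
                    acpa_positive=bool(acpa[i]) if group in ("RA", "HC") else None,
                    sex="M" if male[i] else "F",
                    covariates={k: float(v[i]) for k, v in covs.items()},
                    drug_flags={k: bool(v[i]) for k, v in flags.items()},
                )
            )
    return annotations


def _generate_dilution_series(config, rng, assay_ids):
    series = {}
    copies = 10.0 ** np.arange(2, 7)  # 1e2 .. 1e6 copies per reaction
    for assay in assay_ids:
        ct = (
            config.curve_intercept
            + config.curve_slope * np.log10(copies)
            + config.curve_noise_sd * rng.standard_normal(len(copies))
        )
        series[assay] = DilutionSeries(assay_id=assay, copies=copies, ct=ct)
    return series


# ---------------------------------------------------------------------------
# array phase
# ---------------------------------------------------------------------------

#: planted array-phase screening classes; member counts mirror the modelled
#: study's printed lists (10 fold-change / 3 case-only / 7 p<0.05) plus the
#: manually inspected classes.
ARRAY_FOLD4 = (
    "let-7e", "miR-128", "miR-323-3p", "miR-133b", "miR-18b",
    "miR-144", "miR-451", "miR-150", "miR-486-3p", "miR-196b-5p",
)
ARRAY_CASE_ONLY = ("miR-130b-5p", "miR-452", "miR-579")
ARRAY_P05 = (
    "miR-518d-5p", "miR-202", "miR-193b", "miR-26a",
    "miR-30e-3p", "miR-885-5p", "miR-374b",
)
ARRAY_MANUAL_P10 = ("miR-24", "miR-28-3p")
ARRAY_MANUAL_CT30 = ("miR-28-5p", "miR-125a-5p")
ARRAY_MANUAL_OUTLIER = ("miR-30c", "miR-126-3p")
ARRAY_NORMALIZERS = (
    "miR-93-3p", "miR-223-3p", "miR-339-3p",
    "miR-30a-5p", "miR-301a-5p", "miR-484-5p",
)


@dataclass
class ArrayPhaseConfig:
    """Planted effect sizes of the 3 vs 3 array screening phase (Ct units)."""

    n_case: int = 3
    n_control: int = 3
    n_null: int = 250
    fold4_shift: float = 2.8
    fold4_sd: float = 0.25
    case_only_case_ct: float = 30.0
    case_only_control_ct: float = 44.0  # beyond the detection limit
    p05_shift: float = 1.3
    p05_sd: float = 0.2
    p05_baseline: float = 31.0
    manual_p10_shift: float = 0.5
    manual_p10_sd: float = 0.35
    ct30_shift: float = 1.1
    ct30_sd: float = 0.15
    ct30_baseline: float = 26.0
    outlier_shift: float = 2.3
    outlier_sd: float = 0.1
    outlier_offset: float = 2.5
    null_sd: float = 1.0
    normalizer_sd: float = 0.45
    detection_limit_ct: float = 40.0
    seed: int = 0


def generate_array_phase(config: ArrayPhaseConfig | None = None) -> SyntheticCohort:
    """Small 3 vs 3 array-phase Ct matrix with planted screening classes.

    The truth record maps every planted class to its member assays; null
    assays carry no shift, and the six normalizer candidates are stable,
    highly expressed, and shift-free.
    """
    config = config or ArrayPhaseConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    sample_ids = [f"RA-{i + 1}" for i in range(config.n_case)] + [
        f"HC-{i + 1}" for i in range(config.n_control)
    ]
    is_case = np.r_[np.ones(config.n_case, bool), np.zeros(config.n_control, bool)]
    groups = pd.Series(
        np.where(is_case, "RA", "HC"), index=sample_ids, name="group"
    )

    columns: dict[str, np.ndarray] = {}

    def plant(assay, baseline, sd, shift):
        ct = baseline - shift * is_case + sd * rng.standard_normal(n)
        columns[assay] = ct

    for assay in ARRAY_FOLD4:
        plant(assay, rng.uniform(26, 30), config.fold4_sd, config.fold4_shift)
    for assay in ARRAY_CASE_ONLY:
        ct = np.where(is_case, config.case_only_case_ct, config.case_only_control_ct)
        columns[assay] = ct + 0.3 * rng.standard_normal(n)
    for assay in ARRAY_P05:
        plant(assay, config.p05_baseline, config.p05_sd, config.p05_shift)
    for assay in ARRAY_MANUAL_P10:
        plant(assay, rng.uniform(27, 29), config.manual_p10_sd, config.manual_p10_shift)
    for assay in ARRAY_MANUAL_CT30:
        plant(assay, config.ct30_baseline, config.ct30_sd, config.ct30_shift)
    for assay in ARRAY_MANUAL_OUTLIER:
        ct = (
            config.ct30_baseline
            - config.outlier_shift * is_case
            + config.outlier_sd * rng.standard_normal(n)
        )
        ct[0] += config.outlier_offset  # one case sample looks like a control
        columns[assay] = ct
    for assay in ARRAY_NORMALIZERS:
        plant(assay, rng.uniform(28, 32), config.normalizer_sd, 0.0)
    for i in range(config.n_null):
        plant(f"mir-null-{i + 1:03d}", rng.uniform(24, 34), config.null_sd, 0.0)

    frame = pd.DataFrame(columns, index=sample_ids)
    frame = frame.mask(frame > config.detection_limit_ct)
    ct = CtMatrix(frame.clip(lower=1.0), ~frame.isna(), phase_tag="array")

    truth = {
        "seed": config.seed,
        "classes": {
            "FOLD4": list(ARRAY_FOLD4),
            "CASE_ONLY": list(ARRAY_CASE_ONLY),
            "P05": list(ARRAY_P05),
            "MANUAL_P10": list(ARRAY_MANUAL_P10),
            "MANUAL_CT30_FOLD2": list(ARRAY_MANUAL_CT30),
            "MANUAL_OUTLIER": list(ARRAY_MANUAL_OUTLIER),
        },
        "normalizers": list(ARRAY_NORMALIZERS),
        "n_null": config.n_null,
    }
    annotations = [
        SampleAnnotation(sample_id=s, group=g)
        for s, g in zip(sample_ids, groups)
    ]
    return SyntheticCohort(
        ct=ct,
        annotations=annotations,
        groups=groups,
        dilution_series={},
        truth=truth,
    )


def panel_recovery_config(
    n_per_group: dict[str, int] | None = None,
    effect_ct: float = 2.0,
    sd_ct: float = 2.0,
    seed: int = 0,
) -> CohortConfig:
    """Eight-feature scenario with three informative markers (effect = 1 SD
    by default), for panel-selection recovery studies."""
    informative = ("miR-24", "miR-30c", "miR-125a-5p")
    nulls = ("miR-26a", "miR-28-5p", "miR-28-3p", "miR-30e-3p", "miR-126-3p")
    assays = [
        AssaySpec(a, baseline_ct=DEFAULT_BASELINE_CT[a], sd_ct=sd_ct,
                  shifts={"RA": effect_ct}, role="marker")
        for a in informative
    ] + [
        AssaySpec(a, baseline_ct=DEFAULT_BASELINE_CT[a], sd_ct=sd_ct, role="null")
        for a in nulls
    ]
    return CohortConfig(
        n_per_group=dict(n_per_group or {"RA": 100, "HC": 100}),
        assays=assays,
        correlations=[],
        seed=seed,
    )


def normalizer_comparison_config(seed: int = 0) -> CohortConfig:
    """Stability-verification scenario at n = 48/48.

    Mirrors the study design for confirming normalizer candidates in a
    larger cohort: six shift-free candidate references (raw-Ct SDs around
    one cycle, including the published 1.12 / 1.36 for miR-30a-5p /
    miR-301a-5p), three shifted biomarkers, and a background of null assays
    so that stability methods see a mostly unregulated panel, as on the
    original array.
    """
    sd = 2.0
    markers = [
        AssaySpec(m, baseline_ct=DEFAULT_BASELINE_CT[m], sd_ct=sd,
                  shifts={"RA": shift_for_auc(DEFAULT_MARKER_AUCS[m], sd)},
                  role="marker")
        for m in ("miR-125a-5p", "miR-24", "miR-26a")
    ]
    normalizer_sds = {
        "miR-93-3p": 1.0,
        "miR-223-3p": 0.9,
        "miR-339-3p": 1.05,
        "miR-30a-5p": 1.12,
        "miR-301a-5p": 1.36,
        "miR-484-5p": 0.95,
    }
    normalizers = [
        AssaySpec(a, baseline_ct=28.0 + 0.5 * i, sd_ct=s, role="normalizer")
        for i, (a, s) in enumerate(normalizer_sds.items())
    ]
    nulls = [
        AssaySpec(f"mir-null-{i + 1:02d}", baseline_ct=26.0 + 0.2 * i, sd_ct=1.2,
                  role="null")
        for i in range(30)
    ]
    return CohortConfig(
        n_per_group={"RA": 48, "HC": 48},
        assays=markers + normalizers + nulls,
        correlations=[],
        seed=seed,
    )


def null_cohort_config(
    n_per_group: dict[str, int] | None = None, seed: int = 0
) -> CohortConfig:
    """Default panel with every planted shift removed (AUC 0.5 everywhere)."""
    base = calibrate_to_paper_defaults(seed=seed)
    assays = [replace(spec, shifts={}) for spec in base.assays]
    return replace(
        base,
        assays=assays,
        correlations=[],
        n_per_group=dict(n_per_group or base.n_per_group),
    )
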