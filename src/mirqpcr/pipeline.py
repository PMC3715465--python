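"""End-to-end orchestration of the four discovery phases on synthetic data.

Phases: screen (3 vs 3 array, phase-1 criteria) -> confirm (small cohort,
spike-in normalized t-tests) -> validate (large cohort, absolute
concentrations, ROC with specificity-biased cutoffs, logistic panel /
ePRAM) -> evaluate (OA/SLE negativity, ACPA subgroups, clinical
correlations, age strata, treatment association).  Every phase writes its
tables through :func:`mirqpcr.qpcr_io.write_results`; a run manifest records
the seed and a hash of the configuration so a rerun with the same config
and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic_data
from .diagnostics import marker_report, roc_curve, select_cutoff
from .errors import MirqpcrError
from .evaluation import (
    clinical_correlations,
    control_group_negativity,
    subgroup_sensitivity,
    treatment_association,
)
from .normalization import (
    ct_to_concentration,
    fit_standard_curve,
    global_mean_reference,
    minus_delta_ct,
    spike_in_normalize,
)
from .normalizer_selection import normalizer_report
from .panel_model import (
    addition_check,
    epram_call,
    epram_score,
    fit_logistic,
    lr_test_drop_one,
    select_panel,
    serialize_model,
)
from .qpcr_io import annotations_to_frame, write_results
from .screening import (
    ScreeningConfig,
    delist_assays,
    merge_candidates,
    phase1_select,
    phase2_confirm,
    records_to_frame,
    sort_candidates,
)
from .synthetic_data import EPRAM_FEATURES, SPIKE_ASSAY

log = logging.getLogger("mirqpcr")


@dataclass
class PipelineConfig:
    """Knobs of the default synthetic end-to-end run."""

    seed: int = 0
    output_dir: str = "mirqpcr_run"
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    cutoff_window: float = 0.03
    panel_alpha: float = 0.05
    epram_cutoff: float = 0.50
    confirm_n_per_group: int = 8
    log_conc: bool = True  # correlations/strata on log10 concentration

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run screen -> confirm -> validate -> evaluate on synthetic cohorts.

    Returns the manifest (also written as ``run_manifest.json``).
    """
    config = config or PipelineConfig()
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.as_dict(),
        "phases": {},
    }

    screen_out = run_screen(config)
    manifest["phases"]["screen"] = screen_out["manifest"]
    confirm_out = run_confirm(config, screen_out["panel"])
    manifest["phases"]["confirm"] = confirm_out["manifest"]
    validate_out = run_validate(config, confirm_out["active_panel"])
    manifest["phases"]["validate"] = validate_out["manifest"]
    evaluate_out = run_evaluate(config, validate_out)
    manifest["phases"]["evaluate"] = evaluate_out["manifest"]

    with open(
        os.path.join(config.output_dir, "run_manifest.json"), "w", encoding="utf-8"
    ) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def run_screen(config: PipelineConfig) -> dict:
    """Phase 1: array screening plus normalizer stability on the array."""
    log.info("phase screen: generating 3v3 array cohort")
    cohort = synthetic_data.generate_array_phase(
        synthetic_data.ArrayPhaseConfig(seed=config.seed)
    )
    reference = global_mean_reference(cohort.ct)
    norm = minus_delta_ct(cohort.ct, reference)
    records = phase1_select(norm, cohort.ct, cohort.groups, config.screening)
    audit = records_to_frame(sort_candidates(records))

    normalizer_assays = list(cohort.truth["normalizers"])
    expr = norm.values[normalizer_assays].dropna()
    stability = normalizer_report(cohort.ct, expr, cohort.groups.loc[expr.index])

    panel = merge_candidates(records)
    out_dir = os.path.join(config.output_dir, "screen")
    manifest = write_results(
        {
            "phase1_audit": audit,
            "normalizer_stability": stability,
            "candidate_panel": pd.DataFrame({"assay": panel}),
        },
        out_dir,
    )
    return {"cohort": cohort, "records": records, "panel": panel, "manifest": manifest}


def run_confirm(config: PipelineConfig, panel: list[str]) -> dict:
    """Phase 2: spike-in-normalized confirmation in a small cohort."""
    log.info("phase confirm: %d candidate assays", len(panel))
    base = synthetic_data.calibrate_to_paper_defaults(seed=config.seed + 1)
    n = config.confirm_n_per_group
    base.n_per_group = {"RA": n, "HC": n}
    cohort = synthetic_data.generate_validation_cohort(base)
    norm = spike_in_normalize(cohort.ct, SPIKE_ASSAY)
    # only panel candidates measurable in this cohort are re-tested
    measured = [a for a in panel if a in norm.values.columns]
    values = norm.values[measured] if measured else norm.values
    records, confirmed = phase2_confirm(
        values, cohort.groups, alpha=config.screening.alpha
    )
    qc = {a: r for a, r in synthetic_data_qc_flags().items() if a in confirmed}
    records, active = delist_assays(records, qc, active=confirmed)
    out_dir = os.path.join(config.output_dir, "confirm")
    manifest = write_results(
        {
            "phase2_audit": records_to_frame(records),
            "confirmed": pd.DataFrame({"assay": confirmed}),
            "active_panel": pd.DataFrame({"assay": active}),
        },
        out_dir,
    )
    return {
        "cohort": cohort,
        "confirmed": confirmed,
        "active_panel": active,
        "manifest": manifest,
    }


def synthetic_data_qc_flags() -> dict[str, str]:
    """QC delisting flags for the synthetic panel (none by default).

    The synthetic default panel contains no planted quality failures, so the
    mapping is empty; real runs supply instrument-judged flags here.
    """
    return {}


def run_validate(config: PipelineConfig, active_panel: list[str]) -> dict:
    """Phase 3: absolute quantification, single-marker ROC, ePRAM panel."""
    log.info("phase validate: markers %s", active_panel)
    cohort = synthetic_data.generate_validation_cohort(
        synthetic_data.calibrate_to_paper_defaults(seed=config.seed + 2)
    )
    curves = {
        assay: fit_standard_curve(series)
        for assay, series in cohort.dilution_series.items()
    }
    conc = ct_to_concentration(cohort.ct, curves)
    markers = [a for a in active_panel if a in conc.assay_ids]
    if not markers:
        raise MirqpcrError("validate: no active marker present in cohort")

    case_control = cohort.groups[cohort.groups.isin(["RA", "HC"])]
    cc_conc = conc.conc_pm.loc[case_control.index]
    report = marker_report(
        cc_conc, case_control, markers, window=config.cutoff_window
    )

    features = [*markers, "miR-30a-5p"] if "miR-30a-5p" in conc.assay_ids else markers
    labels = (case_control == "RA").astype(float).to_numpy()
    full, panel = select_panel(
        cc_conc[features], labels, alpha=config.panel_alpha, cutoff=config.epram_cutoff
    )
    lr_table = lr_test_drop_one(full, cc_conc[features], labels)
    additions = addition_check(panel, cc_conc[features], labels, config.panel_alpha)

    epram_features = [f for f in EPRAM_FEATURES if f in conc.assay_ids]
    epram_model = fit_logistic(
        cc_conc[epram_features], labels, cutoff=config.epram_cutoff
    )
    scores = epram_score(epram_model, cc_conc[epram_features])
    epram_roc = select_cutoff(
        roc_curve(scores.to_numpy(), labels.astype(bool)), window=config.cutoff_window
    )

    out_dir = os.path.join(config.output_dir, "validate")
    score_table = pd.DataFrame(
        {
            "sample": scores.index,
            "epram": scores.to_numpy(),
            "call": epram_call(epram_model, cc_conc[epram_features]).to_numpy(),
        }
    )
    manifest = write_results(
        {
            "marker_report": report,
            "panel_lr_tests": lr_table,
            "panel_additions": additions,
            "epram_scores": score_table,
        },
        out_dir,
    )
    with open(os.path.join(out_dir, "epram_model.txt"), "w", encoding="utf-8") as fh:
        fh.write(serialize_model(epram_model))
    return {
        "cohort": cohort,
        "conc": conc,
        "marker_report": report,
        "full_model": full,
        "panel_model": panel,
        "epram_model": epram_model,
        "epram_roc": epram_roc,
        "markers": markers,
        "manifest": manifest,
    }


def run_evaluate(config: PipelineConfig, validate_out: dict) -> dict:
    """Phase 4: specificity cohorts, subgroups, correlations, treatment."""
    cohort = validate_out["cohort"]
    conc = validate_out["conc"]
    report = validate_out["marker_report"].set_index("marker")
    epram_model = validate_out["epram_model"]
    groups = cohort.groups
    ann = annotations_to_frame(cohort.annotations)

    epram_features = list(epram_model.feature_ids)
    scores_all = epram_score(epram_model, conc.conc_pm[epram_features])

    negativity_rows = []
    for group in ("OA", "SLE"):
        idx = groups[groups == group].index
        if not len(idx):
            continue
        for marker in ("miR-24", "miR-125a-5p"):
            if marker not in report.index:
                continue
            frac, n_neg, n_tot = control_group_negativity(
                conc.conc_pm.loc[idx, marker], report.loc[marker, "cutoff"]
            )
            negativity_rows.append(
                {"cohort": group, "test": marker, "negative_fraction": frac,
                 "n_negative": n_neg, "n": n_tot}
            )
        frac, n_neg, n_tot = control_group_negativity(
            scores_all.loc[idx], epram_model.cutoff
        )
        negativity_rows.append(
            {"cohort": group, "test": "ePRAM", "negative_fraction": frac,
             "n_negative": n_neg, "n": n_tot}
        )
    negativity = pd.DataFrame(negativity_rows)

    ra_idx = groups[groups == "RA"].index
    acpa = ann.loc[ra_idx, "acpa_positive"].astype(bool)
    subgroup_tests = [
        (m, conc.conc_pm.loc[ra_idx, m], report.loc[m, "cutoff"])
        for m in ("miR-24", "miR-125a-5p")
        if m in report.index
    ]
    subgroup_tests.append(("ePRAM", scores_all.loc[ra_idx], epram_model.cutoff))
    subgroup_rows = []
    for test, scores, cutoff in subgroup_tests:
        res = subgroup_sensitivity(scores.to_numpy(), cutoff, acpa.to_numpy())
        subgroup_rows.append(
            {
                "test": test,
                "sens_acpa_pos": res["sensitivity_in"],
                "sens_acpa_neg": res["sensitivity_out"],
                "n_acpa_pos": res["n_in"],
                "n_acpa_neg": res["n_out"],
                "fisher_p": res["fisher_p"],
            }
        )
    subgroups = pd.DataFrame(subgroup_rows)

    marker_cols = [m for m in report.index if m in conc.assay_ids]
    values = conc.conc_pm.loc[ra_idx, marker_cols]
    if config.log_conc:
        values = np.log10(values)
    covariate_cols = [
        c for c in ("age", "das28_crp", "crp_mg_l", "esr_mm", "mmp3_ng_ml", "vas_mm")
        if c in ann.columns
    ]
    correlations = clinical_correlations(values, ann.loc[ra_idx, covariate_cols])

    from .evaluation import age_stratified_compare

    cc_idx = groups[groups.isin(["RA", "HC"])].index
    cc_values = conc.conc_pm.loc[cc_idx, marker_cols]
    if config.log_conc:
        cc_values = np.log10(cc_values)
    strata = age_stratified_compare(
        cc_values, groups.loc[cc_idx], ann.loc[cc_idx, "age"]
    )

    flags = ann.loc[ra_idx, ["dmards", "mtx", "steroid", "biologics", "nsaids"]].astype(
        bool
    )
    calls = (scores_all.loc[ra_idx] >= epram_model.cutoff).astype(float)
    treatment = treatment_association(calls.to_numpy(), flags)

    out_dir = os.path.join(config.output_dir, "evaluate")
    manifest = write_results(
        {
            "control_negativity": negativity,
            "acpa_subgroups": subgroups,
            "clinical_correlations": correlations,
            "age_strata": strata,
            "treatment_association": treatment,
        },
        out_dir,
    )
    summary = {
        "negativity": negativity.to_dict(orient="records"),
        "acpa_subgroups": subgroups.to_dict(orient="records"),
    }
    with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"manifest": manifest, "negativity": negativity, "subgroups": subgroups}
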