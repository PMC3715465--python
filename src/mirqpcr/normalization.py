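"""Reference values, -dCt, fold changes and absolute quantification.

-dCt is the log2-scale relative abundance: for sample s and assay a,
``-dCt[s, a] = reference_ct[s] - ct[s, a]``, so a higher value means a more
abundant target (one cycle = one doubling at perfect efficiency).  Fold
changes use efficiency 2 throughout; standard-curve efficiencies are
reported but never re-scale the dCt arithmetic.

Absolute quantification inverts a per-assay standard curve
``ct = slope * log10(copies) + intercept`` to copies per PCR reaction, then
scales to copies per litre of plasma through the extraction/RT/PCR volume
chain and divides by Avogadro's number to yield picomolar concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .qpcr_io import CtMatrix, DilutionSeries

AVOGADRO = 6.02214076e23


@dataclass
class NormalizedMatrix:
    """Samples x assays matrix of -dCt values (NaN where source invalid)."""

    values: pd.DataFrame
    reference_kind: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StandardCurve:
    """Linear Ct-vs-log10(copies) calibration for one assay."""

    assay_id: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(
                f"standard curve for {self.assay_id!r} has non-negative slope"
            )
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared outside [0, 1]")

    @property
    def efficiency(self) -> float:
        """Fractional amplification efficiency, 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_ct(self, ct):
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


@dataclass
class VolumeConfig:
    """Volume chain converting copies per PCR reaction to copies per litre.

    Defaults follow the extraction protocol this pipeline models: 150 ul of
    plasma eluted into 37.5 ul; 5 ul of eluate enters reverse transcription
    and a tenth of the RT product is loaded per PCR reaction.  The RT and
    PCR aliquots are declared defaults (the cited extraction protocol holds
    the exact values) and are logged with every concentration output.
    """

    plasma_volume_ul: float = 150.0
    eluate_volume_ul: float = 37.5
    rt_input_ul: float = 5.0
    pcr_fraction_of_rt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("plasma_volume_ul", "eluate_volume_ul", "rt_input_ul", "pcr_fraction_of_rt"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.rt_input_ul > self.eluate_volume_ul:
            raise ValidationError("rt_input_ul cannot exceed eluate_volume_ul")

    def copies_per_litre(self, copies_per_reaction):
        """Scale copies in one PCR reaction up to copies per litre of plasma."""
        per_rt = np.asarray(copies_per_reaction, dtype=float) / self.pcr_fraction_of_rt
        per_eluate = per_rt * (self.eluate_volume_ul / self.rt_input_ul)
        return per_eluate * (1e6 / self.plasma_volume_ul)

    def as_dict(self) -> dict[str, float]:
        return {
            "plasma_volume_ul": self.plasma_volume_ul,
            "eluate_volume_ul": self.eluate_volume_ul,
            "rt_input_ul": self.rt_input_ul,
            "pcr_fraction_of_rt": self.pcr_fraction_of_rt,
        }


@dataclass
class ConcentrationMatrix:
    """Samples x assays plasma concentrations in pM (NaN where undefined)."""

    conc_pm: pd.DataFrame
    volume_config: VolumeConfig = field(default_factory=VolumeConfig)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.conc_pm.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.conc_pm.columns)


def global_mean_reference(ct: CtMatrix) -> pd.Series:
    """Per-sample mean Ct of all assays with valid amplification."""
    masked = ct.masked()
    counts = masked.notna().sum(axis=1)
    empty = counts[counts == 0]
    if len(empty):
        raise ValidationError(
            "samples with zero valid assays: " + ", ".join(map(str, empty.index))
        )
    return masked.mean(axis=1).rename("reference_ct")


def minus_delta_ct(ct: CtMatrix, reference: pd.Series) -> NormalizedMatrix:
    """-dCt = reference_ct - ct, per cell; invalid cells stay NaN."""
    missing = [s for s in ct.sample_ids if s not in reference.index]
    if missing:
        raise ValidationError(f"reference undefined for samples: {missing}")
    values = ct.masked().rsub(reference.loc[ct.sample_ids], axis=0)
    return NormalizedMatrix(values, reference_kind="global_mean")


def spike_in_normalize(ct: CtMatrix, spike_assay: str) -> NormalizedMatrix:
    """-dCt against the spike-in Ct; the spike column is dropped from output."""
    if spike_assay not in ct.assay_ids:
        raise ValidationError(f"spike-in assay {spike_assay!r} absent from matrix")
    spike_valid = ct.valid[spike_assay]
    bad = spike_valid[~spike_valid]
    if len(bad):
        raise ValidationError(
            f"spike-in {spike_assay!r} invalid in samples: "
            + ", ".join(map(str, bad.index))
        )
    reference = ct.ct[spike_assay]
    rest = [a for a in ct.assay_ids if a != spike_assay]
    values = ct.masked()[rest].rsub(reference, axis=0)
    return NormalizedMatrix(values, reference_kind="spike_in")


def fold_change(group_a_mean_mdct: float, group_b_mean_mdct: float) -> float:
    """Linear fold change between group mean -dCt values (efficiency 2)."""
    return float(2.0 ** (group_a_mean_mdct - group_b_mean_mdct))


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies).

    Requires at least three points spanning two decades of template copies.
    """
    log_copies = np.log10(series.copies)
    if log_copies.max() - log_copies.min() < 2.0 - 1e-9:
        raise ValidationError(
            f"dilution series for {series.assay_id!r} must span >=2 log10 units"
        )
    if np.ptp(log_copies) == 0:
        raise ValidationError("zero variance in log10(copies)")
    fit = stats.linregress(log_copies, series.ct)
    return StandardCurve(
        assay_id=series.assay_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def ct_to_concentration(
    ct: CtMatrix,
    curves: Mapping[str, StandardCurve],
    volume_config: VolumeConfig | None = None,
) -> ConcentrationMatrix:
    """Absolute plasma concentration in pM per valid cell.

    Copies per reaction come from the assay's standard curve; the volume
    chain scales to copies per litre of plasma; dividing by Avogadro's
    number gives mol/l, reported as pM.  Undetermined cells stay undefined
    (NaN), never zero.
    """
    volume_config = volume_config or VolumeConfig()
    missing = [a for a in ct.assay_ids if a not in curves]
    if missing:
        raise ValidationError(f"no standard curve for assays: {missing}")
    masked = ct.masked()
    columns = {}
    for assay in ct.assay_ids:
        copies = curves[assay].copies_from_ct(masked[assay].to_numpy())
        per_litre = volume_config.copies_per_litre(copies)
        columns[assay] = per_litre / AVOGADRO * 1e12  # mol/l -> pM
    conc = pd.DataFrame(columns, index=masked.index)[list(ct.assay_ids)]
    return ConcentrationMatrix(conc_pm=conc, volume_config=volume_config)
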