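"""Reading and writing Ct tables, sample annotations, dilution series and results.

Ct matrices travel as wide delimited text (samples as rows, one header row of
assay ids); a long reader (sample, assay, ct) is provided because instrument
exports vary.  Cells are dot-decimal numbers or an undetermined token
(default ``{"Undetermined", "NA", ""}``).  Undetermined cells are stored as
NaN and flagged invalid; they are never silently coerced to numbers.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CtParseError, StructureError, ValidationError

DEFAULT_UNDETERMINED_TOKENS = ("Undetermined", "NA", "")
GROUP_LABELS = ("RA", "HC", "OA", "SLE")

#: covariates recognised by name in annotation tables (all numeric)
KNOWN_COVARIATES = (
    "das28_esr",
    "das28_crp",
    "crp_mg_l",
    "esr_mm",
    "mmp3_ng_ml",
    "vas_mm",
    "age",
    "sjc",
    "tjc",
    "sledai",
)

#: boolean treatment flags recognised by name
KNOWN_DRUG_FLAGS = ("dmards", "mtx", "steroid", "biologics", "nsaids")


@dataclass
class CtMatrix:
    """Samples x assays threshold-cycle matrix with validity flags.

    ``ct`` holds NaN for undetermined cells.  ``valid`` marks cells with
    valid amplification: by default a cell is valid iff it is determined and
    within ``[ct_min, ct_max]``; instrument validity flags, when supplied,
    may override this (a determined cell may be flagged invalid, never the
    reverse).
    """

    ct: pd.DataFrame
    valid: pd.DataFrame
    phase_tag: str = "array"
    ct_min: float = 0.0
    ct_max: float = 40.0

    def __post_init__(self) -> None:
        if list(self.ct.index) != list(self.valid.index) or list(
            self.ct.columns
        ) != list(self.valid.columns):
            raise StructureError("ct and valid must share index and columns")
        if self.ct.index.has_duplicates:
            raise StructureError("duplicate sample ids")
        if self.ct.columns.has_duplicates:
            raise StructureError("duplicate assay ids")
        vals = self.ct.to_numpy(dtype=float)
        determined = ~np.isnan(vals)
        out_of_range = determined & ((vals < self.ct_min) | (vals > self.ct_max))
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise ValidationError(
                f"Ct {vals[i, j]:g} for sample {self.ct.index[i]!r}, assay "
                f"{self.ct.columns[j]!r} outside [{self.ct_min:g}, {self.ct_max:g}]"
            )
        # undetermined cells are always invalid
        v = self.valid.to_numpy(dtype=bool) & determined
        self.valid = pd.DataFrame(v, index=self.ct.index, columns=self.ct.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.columns)

    def subset_assays(self, assays: Sequence[str]) -> "CtMatrix":
        assays = list(assays)
        return CtMatrix(
            self.ct[assays].copy(),
            self.valid[assays].copy(),
            phase_tag=self.phase_tag,
            ct_min=self.ct_min,
            ct_max=self.ct_max,
        )

    def masked(self) -> pd.DataFrame:
        """Ct values with invalid cells set to NaN."""
        return self.ct.where(self.valid)


@dataclass
class SampleAnnotation:
    """Per-sample group label, serology, clinical covariates and drug flags."""

    sample_id: str
    group: str
    acpa_positive: bool | None = None
    sex: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    drug_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValidationError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        for name, value in self.covariates.items():
            if not np.isfinite(value):
                raise ValidationError(
                    f"covariate {name!r} for sample {self.sample_id!r} not finite"
                )
        age = self.covariates.get("age")
        if age is not None and age < 0:
            raise ValidationError(f"negative age for sample {self.sample_id!r}")


@dataclass
class DilutionSeries:
    """Known copy-number dilution points with measured Ct for one assay."""

    assay_id: str
    copies: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.copies.shape != self.ct.shape:
            raise StructureError("copies and ct must have equal length")
        if len(self.copies) < 3:
            raise ValidationError(
                f"dilution series for {self.assay_id!r} needs >=3 points"
            )
        if (self.copies <= 0).any():
            raise ValidationError("copy numbers must be strictly positive")
        diffs = np.diff(self.copies)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValidationError("copy numbers must be strictly monotone")
        if not np.isfinite(self.ct).all():
            raise ValidationError("dilution Ct values must be finite")


def _parse_cell(
    raw: str, tokens: frozenset[str], sample: str, assay: str
) -> float:
    text = raw.strip()
    if text in tokens:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise CtParseError(
            f"cell for sample {sample!r}, assay {assay!r} is neither numeric "
            f"nor an undetermined token: {raw!r}"
        ) from None


def read_ct_table(
    source,
    *,
    sep: str | None = None,
    undetermined_tokens: Iterable[str] = DEFAULT_UNDETERMINED_TOKENS,
    ct_min: float = 0.0,
    ct_max: float = 40.0,
    phase_tag: str = "array",
) -> CtMatrix:
    """Read a wide Ct table (rows = samples, columns = assays).

    ``sep=None`` sniffs comma vs tab from the header line.  Undetermined
    tokens become NaN cells flagged invalid.  Duplicate sample or assay ids
    raise :class:`StructureError`; an unparseable cell raises
    :class:`CtParseError` naming the offending row and column.
    """
    raw = pd.read_csv(
        source, sep=sep, engine="python", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.columns.has_duplicates:
        raise StructureError("duplicate assay ids in header")
    if raw.index.has_duplicates:
        raise StructureError("duplicate sample ids")
    tokens = frozenset(str(t) for t in undetermined_tokens)
    values = np.empty(raw.shape, dtype=float)
    for i, sample in enumerate(raw.index):
        for j, assay in enumerate(raw.columns):
            values[i, j] = _parse_cell(raw.iat[i, j], tokens, str(sample), str(assay))
    ct = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    valid = ~ct.isna()
    return CtMatrix(ct, valid, phase_tag=phase_tag, ct_min=ct_min, ct_max=ct_max)


def read_ct_table_long(
    source,
    *,
    sample_col: str = "sample",
    assay_col: str = "assay",
    ct_col: str = "ct",
    **kwargs,
) -> CtMatrix:
    """Read a long-format export (one row per sample/assay pair)."""
    long = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in (sample_col, assay_col, ct_col):
        if col not in long.columns:
            raise StructureError(f"long table missing column {col!r}")
    if long.duplicated([sample_col, assay_col]).any():
        raise StructureError("duplicate (sample, assay) pair in long table")
    wide = long.pivot(index=sample_col, columns=assay_col, values=ct_col)
    wide = wide.fillna("")  # absent pairs behave as undetermined
    buf = io.StringIO()
    wide.to_csv(buf)
    buf.seek(0)
    return read_ct_table(buf, **kwargs)


def write_ct_table(matrix: CtMatrix, target, *, undetermined_token: str = "Undetermined") -> None:
    """Write a wide Ct table; NaN cells become the undetermined token."""
    out = matrix.ct.copy()
    out = out.astype(object).where(~matrix.ct.isna(), undetermined_token)
    out.index.name = "sample_id"
    out.to_csv(target)


def read_annotations(
    source,
    *,
    case_insensitive_groups: bool = False,
) -> list[SampleAnnotation]:
    """Read sample annotations from delimited text.

    Requires ``sample_id`` and ``group`` columns.  Columns named in
    :data:`KNOWN_COVARIATES` become numeric covariates; columns named in
    :data:`KNOWN_DRUG_FLAGS` become boolean flags; ``acpa_positive`` and
    ``sex`` are recognised specially.  Unknown numeric columns are preserved
    as covariates; unknown non-numeric columns are ignored with no error.
    """
    table = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    if "sample_id" not in table.columns or "group" not in table.columns:
        raise StructureError("annotation table requires sample_id and group columns")
    if (table["sample_id"].str.strip() == "").any():
        raise StructureError("missing sample_id in annotation table")
    if table["sample_id"].duplicated().any():
        raise StructureError("duplicate sample_id in annotation table")

    annotations = []
    special = {"sample_id", "group", "acpa_positive", "sex"}
    for _, row in table.iterrows():
        group = row["group"].strip()
        if case_insensitive_groups:
            group = group.upper()
        covariates: dict[str, float] = {}
        flags: dict[str, bool] = {}
        for col in table.columns:
            if col in special:
                continue
            text = str(row[col]).strip()
            if text == "" or text == "NA":
                continue
            if col in KNOWN_DRUG_FLAGS:
                flags[col] = _parse_bool(text, col)
            else:
                try:
                    covariates[col] = float(text)
                except ValueError:
                    if col in KNOWN_COVARIATES:
                        raise ValidationError(
                            f"covariate {col!r} not numeric: {text!r}"
                        ) from None
                    continue  # unknown free-text column: ignored
        acpa: bool | None = None
        if "acpa_positive" in table.columns:
            text = str(row["acpa_positive"]).strip()
            if text not in ("", "NA"):
                acpa = _parse_bool(text, "acpa_positive")
        sex = None
        if "sex" in table.columns:
            text = str(row["sex"]).strip()
            sex = text or None
        annotations.append(
            SampleAnnotation(
                sample_id=row["sample_id"].strip(),
                group=group,
                acpa_positive=acpa,
                sex=sex,
                covariates=covariates,
                drug_flags=flags,
            )
        )
    return annotations


def _parse_bool(text: str, col: str) -> bool:
    lowered = text.strip().lower()
    if lowered in ("1", "true", "yes", "y"):
        return True
    if lowered in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"column {col!r}: cannot parse boolean from {text!r}")


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Flatten annotations into one DataFrame indexed by sample_id."""
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "sample_id": ann.sample_id,
            "group": ann.group,
            "acpa_positive": ann.acpa_positive,
            "sex": ann.sex,
        }
        row.update(ann.covariates)
        row.update(ann.drug_flags)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("sample_id")
    return frame


def group_series(annotations: Sequence[SampleAnnotation]) -> pd.Series:
    return pd.Series(
        {a.sample_id: a.group for a in annotations}, name="group", dtype=object
    )


def read_dilution_series(source) -> dict[str, DilutionSeries]:
    """Read standard-curve points from CSV columns (assay, copies, ct)."""
    table = pd.read_csv(source, sep=None, engine="python")
    for col in ("assay", "copies", "ct"):
        if col not in table.columns:
            raise StructureError(f"dilution table missing column {col!r}")
    series = {}
    for assay, sub in table.groupby("assay", sort=False):
        series[str(assay)] = DilutionSeries(
            assay_id=str(assay),
            copies=sub["copies"].to_numpy(float),
            ct=sub["ct"].to_numpy(float),
        )
    return series


def write_results(
    tables: Mapping[str, pd.DataFrame], directory: str | os.PathLike
) -> dict[str, dict[str, object]]:
    """Write named result tables as CSV with a JSON manifest.

    Tables are written in sorted-name order with their existing column order;
    identical inputs produce byte-identical outputs.  Returns the manifest
    (file name and row count per table), which is also written as
    ``manifest.json``.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest: dict[str, dict[str, object]] = {}
    for name in sorted(tables):
        table = tables[name]
        fname = f"{name}.csv"
        path = os.path.join(directory, fname)
        table.to_csv(path, index=False, lineterminator="\n")
        manifest[name] = {"file": fname, "rows": int(len(table))}
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
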