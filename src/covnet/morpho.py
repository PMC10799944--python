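"""Reading, validation and covariate adjustment of regional morphometry tables.

A morphometry table holds one measure — cortical thickness (CT, mm) or
cortical surface area (CSA, mm²) — averaged within each atlas parcel, one
row per subject.  Covariate adjustment regresses each region on an intercept
plus selected subject covariates by ordinary least squares and keeps the
residuals; the interregional correlations of those residuals are the
substrate of the covariance networks.

Missing values are never imputed: with cohorts of ~20 subjects per group a
silently imputed cell would distort the covariance structure the analysis is
about, so validation is strict and failures are fatal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionalAtlas, desikan_atlas, normalize_label

__all__ = [
    "MorphometryTable",
    "CovariateTable",
    "read_regional_table",
    "read_aparc_pair",
    "write_regional_table",
    "residualize",
    "residualize_pair",
    "concat_tables",
]

DEFAULT_COVARIATES = ("age", "sex", "cudit", "audit", "onset_age")


@dataclass(frozen=True)
class MorphometryTable:
    """Subjects × regions matrix of one morphometric measure.

    ``values[s, r]`` is the measure for subject ``subjects[s]`` in region
    ``atlas.region_ids[r]``.  Raw (non-residualized) values must be strictly
    positive; residualized tables may contain any finite real.
    """

    values: np.ndarray
    subjects: tuple[str, ...]
    atlas: RegionalAtlas
    measure: str = "CT"
    group: str = "unknown"
    timepoint: str = "BL"
    residualized: bool = False
    residualized_on: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D subjects × regions matrix")
        if values.shape != (len(self.subjects), self.atlas.n_regions):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.subjects)} subjects × {self.atlas.n_regions} regions"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        if len(self.subjects) < 3:
            raise ValueError(
                "need at least 3 subjects (interregional correlation is "
                "undefined below that)"
            )
        if not np.all(np.isfinite(values)):
            s, r = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing or non-finite value for subject "
                f"{self.subjects[s]!r}, region {self.atlas.region_ids[r]!r}"
            )
        if not self.residualized and np.any(values <= 0):
            s, r = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive raw value for subject {self.subjects[s]!r}, "
                f"region {self.atlas.region_ids[r]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subjects), columns=list(self.atlas.region_ids)
        )


@dataclass(frozen=True)
class CovariateTable:
    """Per-subject covariates: age (years), sex (0/1), CUDIT, AUDIT, onset_age.

    ``onset_age`` (age at first cannabis use) is typically undefined for
    control subjects and may be NaN; it is then dropped from adjustment with
    a warning.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject ids in covariate table")

    def for_subjects(self, subjects: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in subjects if s not in self.data.index]
        if missing:
            raise ValueError(f"covariates missing for subjects: {missing}")
        return self.data.loc[list(subjects)]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0]
    return "\t" if "\t" in header else ","


def _frame_to_table(
    frame: pd.DataFrame,
    atlas: RegionalAtlas,
    measure: str,
    group: str,
    timepoint: str,
    residualized: bool = False,
    residualized_on: tuple[str, ...] = (),
) -> MorphometryTable:
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate subject id {dup!r}")
    colmap: dict[str, str] = {}
    for col in frame.columns:
        colmap.setdefault(normalize_label(str(col)), str(col))
    ordered = []
    for label in atlas.region_ids:
        norm = normalize_label(label)
        if norm not in colmap:
            raise ValueError(f"region column {label!r} is missing from the table")
        ordered.append(colmap[norm])
    sub = frame[ordered]
    for col in ordered:
        coerced = pd.to_numeric(sub[col], errors="coerce")
        bad = coerced.isna() & sub[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric value at row {row!r}, column {col!r}: "
                f"{sub.loc[row, col]!r}"
            )
    values = sub.apply(pd.to_numeric).to_numpy(dtype=float)
    return MorphometryTable(
        values=values,
        subjects=tuple(str(s) for s in frame.index),
        atlas=atlas,
        measure=measure,
        group=group,
        timepoint=timepoint,
        residualized=residualized,
        residualized_on=residualized_on,
    )


def read_regional_table(
    path: str | Path,
    measure: str | None = None,
    atlas: RegionalAtlas | None = None,
    group: str | None = None,
    timepoint: str | None = None,
) -> MorphometryTable:
    """Read a delimited subjects × regions table (CSV or TSV, auto-detected).

    Subject ids are taken from the first column; region columns are matched
    to the atlas case-insensitively after label normalization, and reordered
    to atlas order.  A ``<path>.json`` sidecar written by
    :func:`write_regional_table` supplies measure/group/timepoint defaults.
    """
    path = Path(path)
    atlas = atlas or desikan_atlas()
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frame = pd.read_csv(
        path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip"
    )
    return _frame_to_table(
        frame,
        atlas,
        measure=measure or meta.get("measure", "CT"),
        group=group or meta.get("group", "unknown"),
        timepoint=timepoint or meta.get("timepoint", "BL"),
        residualized=bool(meta.get("residualized", False)),
        residualized_on=tuple(meta.get("residualized_on", ())),
    )


def read_aparc_pair(
    lh_path: str | Path,
    rh_path: str | Path,
    measure: str | None = None,
    atlas: RegionalAtlas | None = None,
    group: str | None = None,
    timepoint: str | None = None,
) -> MorphometryTable:
    """Read a pair of FreeSurfer ``aparcstats2table``-style per-hemisphere tables.

    Columns such as ``lh_bankssts_thickness`` are stripped of their measure
    suffix; non-region summary columns (eTIV, mean thickness, ...) are
    ignored.
    """
    atlas = atlas or desikan_atlas()
    frames = []
    for hemi, path in (("lh", Path(lh_path)), ("rh", Path(rh_path))):
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
        renamed = {}
        for col in frame.columns:
            name = str(col)
            for suffix in ("_thickness", "_area", "_volume"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
            if not name.startswith(("lh", "rh")):
                name = f"{hemi}.{name}"
            renamed[col] = name
        frame = frame.rename(columns=renamed)
        known = {normalize_label(r) for r in atlas.region_ids}
        keep = [c for c in frame.columns if normalize_label(c) in known]
        frames.append(frame[keep])
    merged = pd.concat(frames, axis=1)
    return _frame_to_table(
        merged,
        atlas,
        measure=measure or "CT",
        group=group or "unknown",
        timepoint=timepoint or "BL",
    )


def write_regional_table(table: MorphometryTable, path: str | Path) -> Path:
    """Write the canonical CSV (atlas-ordered columns) plus a JSON sidecar."""
    path = Path(path)
    table.to_frame().rename_axis("subject").to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "measure": table.measure,
                "group": table.group,
                "timepoint": table.timepoint,
                "residualized": table.residualized,
                "residualized_on": list(table.residualized_on),
            },
            indent=2,
        )
    )
    return path


def _design_matrix(
    covs: CovariateTable, subjects: Sequence[str], columns: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    frame = covs.for_subjects(subjects)
    used = []
    cols = []
    for name in columns:
        if name not in frame.columns:
            raise ValueError(f"covariate column {name!r} not found")
        col = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            warnings.warn(
                f"covariate {name!r} has missing values for some subjects; "
                "dropping it from the adjustment",
                stacklevel=3,
            )
            continue
        used.append(name)
        cols.append(col)
    design = np.column_stack([np.ones(len(subjects))] + cols)
    return design, used


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(design)
    flagged = []
    for idx, name in enumerate(names):
        reduced = np.delete(design, idx + 1, axis=1)  # column 0 is the intercept
        if np.linalg.matrix_rank(reduced) == full_rank:
            flagged.append(name)
    return flagged


def residualize(
    table: MorphometryTable,
    covs: CovariateTable,
    columns: Sequence[str] = DEFAULT_COVARIATES,
    force: bool = False,
) -> MorphometryTable:
    """Replace each region's values by OLS residuals on intercept + covariates.

    The fit pools all subjects present in ``table``; to adjust two groups on
    a common model, use :func:`residualize_pair`.  ``columns=[]`` is the
    intercept-only model (per-region demeaning).  Residualizing twice is an
    error unless ``force=True`` (projection makes a second pass a no-op up
    to rounding, which is occasionally worth asserting).
    """
    if table.residualized and not force:
        raise ValueError("table is already residualized")
    columns = [c for c in columns if c in covs.columns]
    design, used = _design_matrix(covs, table.subjects, columns)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        flagged = _collinear_columns(design, used)
        raise ValueError(
            f"rank-deficient covariate design; collinear columns: {flagged}"
        )
    beta, *_ = np.linalg.lstsq(design, table.values, rcond=None)
    resid = table.values - design @ beta
    return replace(
        table,
        values=resid,
        residualized=True,
        residualized_on=tuple(used),
    )


def concat_tables(a: MorphometryTable, b: MorphometryTable) -> MorphometryTable:
    """Stack two tables of the same measure/timepoint (e.g. to pool groups)."""
    if a.atlas.region_ids != b.atlas.region_ids:
        raise ValueError("tables use different atlases")
    if a.measure != b.measure:
        raise ValueError("tables hold different measures")
    if a.residualized != b.residualized:
        raise ValueError("cannot pool residualized with raw values")
    overlap = set(a.subjects) & set(b.subjects)
    if overlap:
        raise ValueError(f"subject ids appear in both tables: {sorted(overlap)}")
    return replace(
        a,
        values=np.vstack([a.values, b.values]),
        subjects=a.subjects + b.subjects,
        group=f"{a.group}+{b.group}",
    )


def residualize_pair(
    a: MorphometryTable,
    b: MorphometryTable,
    covs: CovariateTable,
    columns: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[MorphometryTable, MorphometryTable]:
    """Residualize two groups against one covariate model fitted on the pool.

    Pooling the groups for the fit is the standard covariance-network
    practice: it removes covariate-driven variance while preserving
    between-group differences in the residual covariance, which is the
    object of inference.  Residuals are label-independent, so permutation
    replicates never need to refit.
    """
    pooled = residualize(concat_tables(a, b), covs, columns)
    na = a.n_subjects
    ra = replace(
        a,
        values=pooled.values[:na],
        residualized=True,
        residualized_on=pooled.residualized_on,
    )
    rb = replace(
        b,
        values=pooled.values[na:],
        residualized=True,
        residualized_on=pooled.residualized_on,
    )
    return ra, rb
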