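"""Cohort and longitudinal measurement tables: schemas, validation, scaling.

A *cohort table* holds one row per transplanted subject:
``id, time_years, event, age, sex, weight`` where ``time_years`` is the time
from transplantation to allograft failure or censoring (years, > 0) and
``event`` is 1 for failure, 0 for censoring.

A *longitudinal table* holds one row per follow-up visit:
``id, obstime, hematocrit, proteinuria, gfr``; any biomarker cell may be
empty (missing), and missingness is resolved only later by the landmarking
carry-forward rule, never at read time.

Covariates enter the models on conventional clinical scales (age per 10
years, weight per 10 kg, hematocrit per 10 percentage points, GFR per
10 ml/min, proteinuria per 1 g/24 h, sex coded male=0 / female=1), handled
by :class:`CovariateSpec` and :func:`apply_scaling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

COHORT_COLUMNS = ["id", "time_years", "event", "age", "sex", "weight"]
LONGITUDINAL_COLUMNS = ["id", "obstime", "hematocrit", "proteinuria", "gfr"]
BIOMARKERS = ["hematocrit", "proteinuria", "gfr"]


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. non-positive survival time)."""


class CodingError(ValueError):
    """A categorical value has no entry in the covariate's coding map."""


@dataclass(frozen=True)
class CovariateSpec:
    """How one covariate is measured, scaled and (if categorical) coded.

    Parameters
    ----------
    name : column name in the cohort or longitudinal table.
    role : ``"baseline"`` (measured once, at transplantation) or
        ``"longitudinal"`` (re-measured at follow-up visits).
    scale_divisor : raw values are divided by this before modelling, so a
        coefficient is a log hazard ratio per ``scale_divisor`` raw units.
    coding : optional category -> number map applied before scaling.
    """

    name: str
    role: str = "baseline"
    scale_divisor: float = 1.0
    coding: dict | None = None

    def __post_init__(self):
        if self.role not in ("baseline", "longitudinal"):
            raise ValueError(f"role must be baseline/longitudinal, got {self.role!r}")
        if not self.scale_divisor > 0:
            raise ValueError("scale_divisor must be > 0")


def default_covariate_specs() -> list[CovariateSpec]:
    """The six-predictor convention of the renal allograft analysis.

    Age per 10 years, weight per 10 kg, hematocrit per 10 percentage points
    of blood volume, GFR per 10 ml/min, proteinuria per 1 g/24 h, and sex
    coded male=0 / female=1.
    """
    return [
        CovariateSpec("age", "baseline", 10.0),
        CovariateSpec("sex", "baseline", 1.0, coding={"male": 0, "female": 1}),
        CovariateSpec("weight", "baseline", 10.0),
        CovariateSpec("hematocrit", "longitudinal", 10.0),
        CovariateSpec("proteinuria", "longitudinal", 1.0),
        CovariateSpec("gfr", "longitudinal", 10.0),
    ]


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants; returns the frame with canonical column order."""
    _require_columns(cohort, COHORT_COLUMNS, "cohort")
    if cohort["id"].duplicated().any():
        dupes = cohort.loc[cohort["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate subject id(s): {dupes[:5]}")
    bad_time = cohort["time_years"] <= 0
    if bad_time.any():
        ids = cohort.loc[bad_time, "id"].tolist()
        raise ValidationError(
            f"time_years must be > 0; violated by id(s): {ids[:5]}"
        )
    if not cohort["event"].isin([0, 1]).all():
        ids = cohort.loc[~cohort["event"].isin([0, 1]), "id"].tolist()
        raise ValidationError(f"event must be 0/1; violated by id(s): {ids[:5]}")
    return cohort[COHORT_COLUMNS + [c for c in cohort.columns if c not in COHORT_COLUMNS]]


def validate_longitudinal(
    measurements: pd.DataFrame, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Check visit invariants and return the table sorted by (id, obstime)."""
    _require_columns(measurements, LONGITUDINAL_COLUMNS, "longitudinal")
    if (measurements["obstime"] < 0).any():
        ids = measurements.loc[measurements["obstime"] < 0, "id"].tolist()
        raise ValidationError(f"obstime must be >= 0; violated by id(s): {ids[:5]}")
    if cohort is not None:
        unknown = set(measurements["id"]) - set(cohort["id"])
        if unknown:
            raise ValidationError(
                f"longitudinal id(s) absent from cohort: {sorted(unknown)[:5]}"
            )
    out = measurements.sort_values(["id", "obstime"], kind="mergesort")
    return out.reset_index(drop=True)


def read_cohort(
    path, rename: dict[str, str] | None = None, validate: bool = True
) -> pd.DataFrame:
    """Read a cohort CSV (one row per subject) with raw, unscaled values.

    ``rename`` maps native column names to the canonical ones, so the public
    renal dataset's headers can be used directly.
    """
    frame = pd.read_csv(path)
    if rename:
        frame = frame.rename(columns=rename)
    return validate_cohort(frame) if validate else frame


def read_longitudinal(
    path,
    rename: dict[str, str] | None = None,
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a visit-level CSV; empty biomarker cells become NaN (never zero)."""
    frame = pd.read_csv(path)
    if rename:
        frame = frame.rename(columns=rename)
    return validate_longitudinal(frame, cohort=cohort)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_longitudinal(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False)


def apply_scaling(
    frame: pd.DataFrame, specs: list[CovariateSpec]
) -> pd.DataFrame:
    """Divide each covariate by its divisor; code categories numerically.

    Columns named in ``specs`` but absent from ``frame`` are ignored, so the
    same spec list serves both the cohort and the longitudinal table. The
    transform is invertible via :func:`invert_scaling` (categories excepted,
    which round-trip through their codes).
    """
    out = frame.copy()
    for spec in specs:
        if spec.name not in out.columns:
            continue
        col = out[spec.name]
        if spec.coding is not None:
            known = col.isin(spec.coding) | col.isna()
            if not known.all():
                bad = sorted(set(col[~known].astype(str)))
                raise CodingError(
                    f"unknown {spec.name} categor(ies): {bad[:5]}; "
                    f"expected one of {sorted(map(str, spec.coding))}"
                )
            col = col.map(spec.coding)
        out[spec.name] = col.astype(float) / spec.scale_divisor
    return out


def invert_scaling(frame: pd.DataFrame, specs: list[CovariateSpec]) -> pd.DataFrame:
    """Undo :func:`apply_scaling` (categorical columns stay numerically coded)."""
    out = frame.copy()
    for spec in specs:
        if spec.name not in out.columns or spec.coding is not None:
            continue
        out[spec.name] = out[spec.name].astype(float) * spec.scale_divisor
    return out
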