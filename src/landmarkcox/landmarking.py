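"""Landmark datasets and the stacked super-dataset.

Landmarking turns one survival dataset into a family of conditional ones: at
each landmark time ``s_l`` on an equidistant grid, keep the subjects still at
risk (``T > s_l``), evaluate their covariates as of ``s_l`` (last observation
carried forward), and administratively censor the window at ``s_l + w`` —
events after the window end are ignored. Stacking every landmark dataset
``R_l`` gives the super-dataset ``R`` on which a single Cox model with
landmark-time interactions is fitted.

Conventions (documented, since published analyses rarely state them):

* LOCF takes the *latest visit record* at or before ``s_l``; if that record's
  cell for a biomarker is empty the value is missing at ``s_l``.
* Subjects with any unresolvable model biomarker at ``s_l`` are excluded from
  ``R_l`` (counted, never silently imputed).
* ``T == s_l`` exactly means *not* at risk (left-open risk sets, matching the
  fitting engine's ``entry < t <= exit`` convention).
* The event window is half-open ``(s_l, s_l + w]``: an event exactly at the
  window end still counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BIOMARKERS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkGrid:
    """Equidistant prediction-time grid [s0, sL] with window w (years)."""

    s0: float
    sL: float
    spacing: float
    w: float

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.sL - self.s0) / self.spacing))
        return self.s0 + self.spacing * np.arange(n + 1)

    @property
    def span(self) -> float:
        """Standardisation denominator s_L - s_0 for the scaled time u."""
        return self.sL - self.s0

    def u(self, s: float | np.ndarray) -> float | np.ndarray:
        """Scaled landmark time u = (s - s0) / (sL - s0), in [0, 1] on grid."""
        return (np.asarray(s) - self.s0) / self.span


def make_grid(s0: float, sL: float, spacing: float, w: float) -> LandmarkGrid:
    """Build the landmark grid; the span must be a whole number of spacings.

    The default analysis grid is ``make_grid(0, 10, 0.25, 5)``: 41 landmark
    points every 3 months on the first ten post-transplant years, each
    opening a 5-year prediction window.
    """
    if not sL > s0:
        raise ValueError("need sL > s0")
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    ratio = (sL - s0) / spacing
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        nearest = (sL - s0) / max(1, round(ratio))
        raise ValueError(
            f"(sL - s0) = {sL - s0} is not a multiple of spacing {spacing}; "
            f"nearest valid spacing is {nearest:g}"
        )
    if not w > 0:
        raise ValueError("window w must be > 0")
    return LandmarkGrid(s0=float(s0), sL=float(sL), spacing=float(spacing), w=float(w))


def covariate_at(
    measurements: pd.DataFrame, s_l: float, biomarker: str
) -> float:
    """LOCF value of one biomarker for one subject at landmark ``s_l``.

    ``measurements`` holds one subject's visits sorted by ``obstime``. The
    value is taken from the latest visit with ``obstime <= s_l``; NaN is
    returned when no such visit exists or when that visit's cell is empty.
    """
    eligible = measurements[measurements["obstime"] <= s_l]
    if len(eligible) == 0:
        return float("nan")
    return float(eligible.iloc[-1][biomarker])


def _locf_at(measurements: pd.DataFrame, s_l: float, columns: list[str]) -> pd.DataFrame:
    """Latest visit record at or before s_l, per subject (vectorised LOCF)."""
    eligible = measurements[measurements["obstime"] <= s_l]
    eligible = eligible.sort_values(["id", "obstime"], kind="mergesort")
    last = eligible.drop_duplicates("id", keep="last")
    return last[["id"] + columns]


@dataclass
class StackedLandmarkDataset:
    """The super-dataset R: one row per (subject, landmark) pair.

    ``rows`` columns: ``id, landmark, entry, exit, status`` plus the
    landmark-evaluated (scaled) covariates. ``n_excluded`` counts at-risk
    subjects dropped for unresolvable biomarkers, per landmark.
    """

    rows: pd.DataFrame
    grid: LandmarkGrid
    n_excluded: dict[float, int] = field(default_factory=dict)

    @property
    def cluster(self) -> np.ndarray:
        return self.rows["id"].to_numpy()

    def landmark_sizes(self) -> pd.Series:
        return self.rows.groupby("landmark").size()

    def write_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def build_landmark_dataset(
    cohort: pd.DataFrame,
    measurements: pd.DataFrame,
    s_l: float,
    w: float,
    biomarkers: list[str] | None = None,
    baseline_covariates: list[str] = ("age", "sex", "weight"),
) -> pd.DataFrame:
    """One landmark dataset R_l (a frame of landmark rows).

    Inputs are expected on the model (scaled) scale. Subjects enter iff
    ``time_years > s_l``; exit is ``min(T, s_l + w)`` and status is 1 only
    for events inside the half-open window ``(s_l, s_l + w]``.
    """
    if biomarkers is None:
        biomarkers = list(BIOMARKERS)
    at_risk = cohort[cohort["time_years"] > s_l]
    if len(at_risk) == 0:
        logger.warning("empty risk set at landmark %.3g", s_l)
        return _empty_rows(biomarkers, baseline_covariates)
    out = at_risk[["id", "time_years", "event"] + list(baseline_covariates)].copy()
    if biomarkers:
        locf = _locf_at(measurements, s_l, biomarkers)
        out = out.merge(locf, on="id", how="left")
        resolvable = out[biomarkers].notna().all(axis=1)
        n_dropped = int((~resolvable).sum())
        if n_dropped:
            logger.info(
                "landmark %.3g: dropped %d at-risk subject(s) with unresolvable "
                "biomarker values", s_l, n_dropped,
            )
        out = out[resolvable]
        out.attrs["n_excluded"] = n_dropped
    horizon = s_l + w
    out["landmark"] = s_l
    out["entry"] = s_l
    out["exit"] = np.minimum(out["time_years"], horizon)
    out["status"] = ((out["event"] == 1) & (out["time_years"] <= horizon)).astype(int)
    cols = ["id", "landmark", "entry", "exit", "status"] + list(baseline_covariates) + biomarkers
    result = out[cols].reset_index(drop=True)
    result.attrs["n_excluded"] = out.attrs.get("n_excluded", 0)
    return result


def _empty_rows(biomarkers, baseline_covariates) -> pd.DataFrame:
    cols = ["id", "landmark", "entry", "exit", "status"] + list(baseline_covariates) + list(biomarkers)
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


def stack(
    cohort: pd.DataFrame,
    measurements: pd.DataFrame,
    grid: LandmarkGrid,
    biomarkers: list[str] | None = None,
    baseline_covariates: list[str] = ("age", "sex", "weight"),
) -> StackedLandmarkDataset:
    """Stack all landmark datasets R_l into the super-dataset R.

    Row order is deterministic: by landmark, then by subject order within the
    cohort. Each subject re-appears once per landmark it is at risk for, so
    downstream variance estimation must cluster on ``id``.
    """
    if biomarkers is None:
        biomarkers = list(BIOMARKERS)
    measurements = measurements.sort_values(["id", "obstime"], kind="mergesort")
    parts, excluded = [], {}
    for s_l in grid.points:
        r_l = build_landmark_dataset(
            cohort, measurements, float(s_l), grid.w,
            biomarkers=biomarkers, baseline_covariates=baseline_covariates,
        )
        excluded[float(s_l)] = r_l.attrs.get("n_excluded", 0)
        if len(r_l):
            parts.append(r_l)
    if parts:
        rows = pd.concat(parts, ignore_index=True)
    else:
        rows = _empty_rows(biomarkers, baseline_covariates)
    return StackedLandmarkDataset(rows=rows, grid=grid, n_excluded=excluded)
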