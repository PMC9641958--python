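"""Per-landmark predictive performance: Harrell's C, IPCW Brier, Monte Carlo CV.

Discrimination is Harrell's pairwise concordance computed within each
landmark dataset on the administratively censored window: a pair is usable
iff the smaller observed time is an event; tied risk scores count 1/2.

Calibration is the inverse-probability-of-censoring-weighted (IPCW) Brier
score at horizon s_l + w: subjects who fail inside the window are weighted by
1/G(T-), subjects surviving the window by 1/G(horizon-), and subjects
censored inside the window get weight 0, with G the Kaplan-Meier estimate of
the censoring distribution on the evaluation set. Without censoring every
weight is 1 and the score is the plain mean squared error.

Monte Carlo cross-validation repeats a subject-level train/test split,
refits the dynamic and static models on the training subjects, evaluates on
the held-out subjects at every landmark, and averages per landmark and
overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarking import LandmarkGrid
from .model import BasisSpec, LandmarkSuperModel, StaticCoxModel

logger = logging.getLogger(__name__)


def harrell_c(risk_scores, times, status) -> float:
    """Harrell's concordance: concordant usable pairs / usable pairs.

    A pair (i, j) with t_i < t_j is usable iff subject i had the event; it is
    concordant when risk_i > risk_j, and tied risks contribute 1/2. Pairs
    with identical times are never usable.
    """
    risk = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    if not len(risk) == len(t) == len(d):
        raise ValueError("inputs must have equal length")
    usable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no comparable pairs")
    diff = risk[:, None] - risk[None, :]
    concordant = (usable & (diff > 0)).sum() + 0.5 * (usable & (diff == 0)).sum()
    return float(concordant / n_usable)


def _censoring_survival(times: np.ndarray, status: np.ndarray):
    """Kaplan-Meier of the censoring distribution; returns a left-limit G(t-)."""
    order = np.argsort(times, kind="mergesort")
    t, d = times[order], 1 - status[order]  # censorings are the "events"
    uniq, idx = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - idx
    cens = np.add.reduceat(d, idx)
    g = np.cumprod(1.0 - cens / at_risk)

    def g_minus(x: np.ndarray) -> np.ndarray:
        # G just before x: product over censoring times strictly < x
        i = np.searchsorted(uniq, np.asarray(x, dtype=float), side="left")
        gg = np.concatenate([[1.0], g])
        return gg[i]

    return g_minus


def brier_ipcw(predicted_survival, times, status, horizon: float) -> float:
    """IPCW Brier score of predicted survival-to-horizon probabilities.

    ``predicted_survival[i]`` is subject i's predicted probability of
    surviving past ``horizon``; ``times``/``status`` are the observed
    follow-up on the same clock as ``horizon``.
    """
    p_surv = np.asarray(predicted_survival, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    if np.any((p_surv < 0) | (p_surv > 1)):
        raise ValueError("predicted survival must lie in [0, 1]")
    g_minus = _censoring_survival(t, d)
    if g_minus(np.array([horizon]))[0] <= 0:
        raise ValueError("inestimable weights: censoring survival reaches 0")
    event_by_h = (t <= horizon) & (d == 1)
    survived = t > horizon
    # administrative censoring exactly at the horizon counts as surviving it
    survived = survived | ((t == horizon) & (d == 0))
    w = np.zeros(len(t))
    if event_by_h.any():
        g_ev = g_minus(t[event_by_h])
        if np.any(g_ev <= 0):
            raise ValueError("inestimable weights: censoring survival reaches 0")
        w[event_by_h] = 1.0 / g_ev
    if survived.any():
        g_h = g_minus(np.array([horizon]))[0]
        if g_h <= 0:
            raise ValueError("inestimable weights: censoring survival reaches 0")
        w[survived] = 1.0 / g_h
    p_event = 1.0 - p_surv
    outcome = event_by_h.astype(float)
    return float(np.mean(w * (outcome - p_event) ** 2))


@dataclass
class MetricCurve:
    """One metric traced over the landmark grid, plus its cross-landmark mean."""

    metric: str  # "cindex" | "brier"
    model: str  # "dynamic" | "static"
    window: float
    landmark_times: np.ndarray
    values: np.ndarray  # NaN where the landmark was unevaluable

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "metric": self.metric,
                "window": self.window,
                "landmark": self.landmark_times,
                "value": self.values,
            }
        )


def evaluate_per_landmark(
    model,
    cohort: pd.DataFrame,
    measurements: pd.DataFrame,
    grid: LandmarkGrid,
    w: float | None = None,
    label: str | None = None,
) -> tuple[MetricCurve, MetricCurve]:
    """C-index and Brier score of ``model`` at every landmark of ``grid``.

    ``model`` is a fitted :class:`LandmarkSuperModel` or
    :class:`StaticCoxModel` (anything with ``predict_at_landmark``); the
    evaluation subjects must be disjoint from the training subjects for the
    result to be honest. Risk is 1 - predicted w-year conditional survival.
    Landmarks with fewer than two evaluable subjects, no usable pairs, or
    inestimable censoring weights are recorded as NaN and excluded from the
    mean.
    """
    w = grid.w if w is None else w
    if label is None:
        label = "dynamic" if isinstance(model, LandmarkSuperModel) else "static"
    cvals = np.full(len(grid.points), np.nan)
    bvals = np.full(len(grid.points), np.nan)
    for i, s_l in enumerate(grid.points):
        s_l = float(s_l)
        pred = model.predict_at_landmark(cohort, measurements, s_l, w)
        if len(pred) < 2:
            logger.info("landmark %.3g: fewer than 2 evaluable subjects", s_l)
            continue
        sub = cohort[cohort["id"].isin(pred["id"])].merge(pred, on="id")
        horizon = s_l + w
        exit_ = np.minimum(sub["time_years"].to_numpy(float), horizon)
        status = ((sub["event"] == 1) & (sub["time_years"] <= horizon)).to_numpy(int)
        risk = 1.0 - sub["survival"].to_numpy(float)
        try:
            cvals[i] = harrell_c(risk, exit_, status)
        except ValueError:
            logger.info("landmark %.3g: no usable pairs for the C-index", s_l)
        try:
            bvals[i] = brier_ipcw(sub["survival"].to_numpy(float), exit_, status, horizon)
        except ValueError:
            logger.info("landmark %.3g: inestimable Brier weights", s_l)
    return (
        MetricCurve("cindex", label, w, grid.points, cvals),
        MetricCurve("brier", label, w, grid.points, bvals),
    )


@dataclass(frozen=True)
class CVPlan:
    """Monte Carlo cross-validation plan: subject-level random splits."""

    iterations: int = 200
    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def monte_carlo_cv(
    cohort: pd.DataFrame,
    measurements: pd.DataFrame,
    grid: LandmarkGrid,
    plan: CVPlan,
    basis: BasisSpec | None = None,
    windows: tuple[float, ...] | None = None,
    models: tuple[str, ...] = ("dynamic", "static"),
    max_skip_fraction: float = 0.1,
) -> pd.DataFrame:
    """Repeated subject-level train/test evaluation of both models.

    Each iteration draws a train fraction of *subjects*, fits the requested
    models on the training tables and evaluates them per landmark on the
    held-out subjects. Returns a tidy frame
    ``model, metric, window, landmark, value`` where ``value`` is the mean
    over iterations (missing landmark cells excluded); rows with
    ``landmark = NaN`` carry each curve's overall cross-landmark mean.
    Deterministic for a fixed plan seed. Iterations whose training set cannot
    be fitted are skipped; more than ``max_skip_fraction`` skips is an error.
    """
    windows = (grid.w,) if windows is None else windows
    rng = np.random.default_rng(plan.seed)
    ids = cohort["id"].to_numpy()
    n_train = int(round(plan.train_fraction * len(ids)))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("train_fraction leaves an empty train or test set")
    per_iter: list[pd.DataFrame] = []
    n_skipped = 0
    for it in range(plan.iterations):
        train_ids = rng.choice(ids, size=n_train, replace=False)
        train_mask = cohort["id"].isin(train_ids)
        train_c, test_c = cohort[train_mask], cohort[~train_mask]
        train_m = measurements[measurements["id"].isin(train_c["id"])]
        test_m = measurements[measurements["id"].isin(test_c["id"])]
        try:
            fitted = {}
            if "dynamic" in models:
                fitted["dynamic"] = LandmarkSuperModel(
                    s0=grid.s0, s_max=grid.sL, spacing=grid.spacing,
                    window=grid.w, basis=basis,
                ).fit(train_c, train_m)
            if "static" in models:
                fitted["static"] = StaticCoxModel().fit(train_c, train_m)
        except Exception as err:  # unfittable training split
            n_skipped += 1
            logger.warning("iteration %d skipped: %s", it, err)
            continue
        for w in windows:
            for label, mod in fitted.items():
                ccurve, bcurve = evaluate_per_landmark(
                    mod, test_c, test_m, grid, w=w, label=label
                )
                frame = pd.concat([ccurve.to_frame(), bcurve.to_frame()])
                frame["iteration"] = it
                per_iter.append(frame)
    if n_skipped > plan.iterations * max_skip_fraction:
        raise RuntimeError(
            f"{n_skipped}/{plan.iterations} CV iterations were unfittable"
        )
    tall = pd.concat(per_iter, ignore_index=True)
    keys = ["model", "metric", "window", "landmark"]
    by_landmark = tall.groupby(keys, as_index=False)["value"].mean()
    overall = (
        by_landmark.groupby(["model", "metric", "window"], as_index=False)["value"]
        .mean()
        .assign(landmark=np.nan)
    )
    return pd.concat([by_landmark, overall[by_landmark.columns]], ignore_index=True)
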