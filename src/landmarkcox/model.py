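"""The landmark super-model and its static baseline comparator.

The dynamic Cox model fitted on the stacked landmark dataset R is

    h(t | Z, s_l) = h0(t) * exp( Z(s_l)' beta(s_l) + theta(s_l) ),
    s_l < t <= s_l + w,

where each covariate's log hazard ratio is a polynomial in the standardised
landmark time u = (s_l - s0)/(sL - s0),

    beta_k(u) = beta_{k,0} + beta_{k,1} u + ... + beta_{k,d_k} u^{d_k},

and theta(u) = theta_1 u + ... + theta_q u^q shifts the baseline hazard
proportionally across landmarks (no constant term: it would be absorbed by
h0). One common baseline hazard is shared by all landmarks.

Conditional w-year survival from landmark s_l is

    S(s_l + w | s_l, Z) = exp( - sum_{t_j in (s_l, s_l+w]} dH0(t_j) e^{lp} ),

with lp the expanded design row (theta terms included) dotted with the
coefficients, and dH0 the Breslow increments of the super-model fit.

The standardised dynamic hazard ratio of covariate k at landmark s is

    HR^w(s) = exp( beta_{k,0} + beta_{k,1} u + ... + beta_{k,d} u^d ),

with a Wald interval from the (cluster-robust, by default) covariance block.

Both models are exposed as sklearn-style estimators (`fit`, predict methods,
trailing-underscore fitted attributes) so they compose with standard
model-selection tooling; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import cox_engine
from .cox_engine import BaselineHazard, CoxFit
from .data_model import (
    BIOMARKERS,
    CovariateSpec,
    apply_scaling,
    default_covariate_specs,
    validate_cohort,
    validate_longitudinal,
)
from .landmarking import LandmarkGrid, StackedLandmarkDataset, make_grid, stack, _locf_at

logger = logging.getLogger(__name__)


def _default_degrees() -> dict[str, int]:
    # The renal study's retained structure: constant effects for age and
    # weight, linear-in-u effects for hematocrit and GFR, quadratic for
    # proteinuria; sex not retained.
    return {"age": 0, "weight": 0, "hematocrit": 1, "gfr": 1, "proteinuria": 2}


@dataclass(frozen=True)
class BasisSpec:
    """Polynomial degrees of the time-varying effect and time functions.

    ``degrees[name] = d`` expands covariate ``name`` into columns
    ``z, z*u, ..., z*u^d``; ``theta_degree = q`` adds columns ``u, ..., u^q``.
    """

    degrees: dict[str, int] = field(default_factory=_default_degrees)
    theta_degree: int = 2

    def __post_init__(self):
        for name, d in self.degrees.items():
            if d not in (0, 1, 2):
                raise ValueError(f"degree for {name!r} must be in {{0,1,2}}, got {d}")
        if self.theta_degree < 0:
            raise ValueError("theta_degree must be >= 0")

    @property
    def covariates(self) -> list[str]:
        return list(self.degrees)

    @property
    def column_names(self) -> list[str]:
        cols = []
        for name, d in self.degrees.items():
            cols.append(name)
            cols.extend(f"{name}:u^{k}" if k > 1 else f"{name}:u" for k in range(1, d + 1))
        cols.extend(
            f"theta:u^{k}" if k > 1 else "theta:u" for k in range(1, self.theta_degree + 1)
        )
        return cols

    @property
    def n_columns(self) -> int:
        return sum(d + 1 for d in self.degrees.values()) + self.theta_degree

    def covariate_slice(self, name: str) -> slice:
        """Column positions of covariate ``name``'s basis terms."""
        start = 0
        for k, d in self.degrees.items():
            if k == name:
                return slice(start, start + d + 1)
            start += d + 1
        raise KeyError(f"covariate {name!r} is not in the basis")


def expand_basis(
    z: pd.DataFrame | dict, s_l: np.ndarray | float, grid: LandmarkGrid, spec: BasisSpec
) -> np.ndarray:
    """Design rows for covariates ``z`` evaluated at landmark time(s) ``s_l``.

    ``z`` maps covariate name to scaled value(s); scalar and vector inputs
    broadcast. Covariate columns come first (grouped per covariate, ascending
    power of u), then the theta columns ``u, ..., u^q``.
    """
    u = np.atleast_1d(np.asarray(grid.u(s_l), dtype=float))
    keys = z.columns if isinstance(z, pd.DataFrame) else z
    vals = {}
    n = len(u)
    for name in spec.degrees:
        if name not in keys:
            raise KeyError(f"covariate {name!r} missing from input")
        v = np.atleast_1d(np.asarray(z[name], dtype=float))
        vals[name] = v
        n = max(n, len(v))
    u = np.broadcast_to(u, (n,))
    cols = []
    for name, d in spec.degrees.items():
        val = np.broadcast_to(vals[name], (n,))
        for k in range(d + 1):
            cols.append(val * u**k)
    for k in range(1, spec.theta_degree + 1):
        cols.append(u**k)
    return np.column_stack(cols) if cols else np.empty((n, 0))


@dataclass
class SuperModelFit:
    """A fitted landmark super-model: coefficients, covariance and baseline."""

    basis: BasisSpec
    cox: CoxFit
    baseline: BaselineHazard
    grid: LandmarkGrid

    def linear_predictor(self, z, s_l) -> np.ndarray:
        return expand_basis(z, s_l, self.grid, self.basis) @ self.cox.coefficients


def fit_supermodel(
    stacked: StackedLandmarkDataset, spec: BasisSpec | None = None, robust: bool = True
) -> SuperModelFit:
    """Fit the dynamic Cox model on a stacked landmark dataset.

    Rows are counting-process records (entry = landmark, exit, status) with
    the subject as the variance cluster; the Breslow baseline hazard of the
    shared h0(t) is attached to the returned fit.
    """
    spec = spec if spec is not None else BasisSpec()
    rows = stacked.rows
    if len(rows) == 0:
        raise ValueError("stacked dataset is empty")
    design = expand_basis(rows, rows["landmark"].to_numpy(), stacked.grid, spec)
    fit = cox_engine.fit_partial_likelihood(
        design,
        rows["entry"].to_numpy(float),
        rows["exit"].to_numpy(float),
        rows["status"].to_numpy(int),
        cluster_ids=stacked.cluster,
        column_names=spec.column_names,
    )
    baseline = cox_engine.breslow_baseline(
        rows["entry"].to_numpy(float),
        rows["exit"].to_numpy(float),
        rows["status"].to_numpy(int),
        design @ fit.coefficients,
    )
    return SuperModelFit(basis=spec, cox=fit, baseline=baseline, grid=stacked.grid)


def predict_dynamic_survival(
    fit: SuperModelFit, z, s_l: float, w: float | None = None
) -> float | np.ndarray:
    """Conditional survival S(s_l + w | s_l, Z) from the super-model.

    ``z`` may hold scalars (one subject) or equal-length vectors (many);
    landmark times between grid points are allowed (u is evaluated
    continuously), but s_l must lie inside [s0, sL].
    """
    grid = fit.grid
    if not (grid.s0 - 1e-9 <= s_l <= grid.sL + 1e-9):
        raise ValueError(f"s_l = {s_l} outside the landmark interval [{grid.s0}, {grid.sL}]")
    w = grid.w if w is None else w
    lp = fit.linear_predictor(z, s_l)
    h0 = fit.baseline.window_hazard(s_l, s_l + w)
    out = np.exp(-h0 * np.exp(lp))
    return float(out[0]) if out.size == 1 else out


@dataclass
class DynamicHR:
    """Standardised dynamic hazard ratio curve of one covariate."""

    covariate: str
    landmark_times: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark": self.landmark_times,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def dynamic_hr(
    fit: SuperModelFit,
    covariate: str,
    s_values: np.ndarray | None = None,
    robust: bool = True,
    alpha: float = 0.05,
) -> DynamicHR:
    """HR^w(s) = exp(beta_0 + beta_1 u + ... + beta_d u^d) with Wald CIs.

    The variance of the log HR at each s is c' Sigma c with
    c = (1, u, ..., u^d) and Sigma the covariance block of the covariate's
    basis coefficients (cluster-robust by default).
    """
    if covariate not in fit.basis.degrees:
        raise KeyError(f"covariate {covariate!r} is not in the fitted basis")
    s = fit.grid.points if s_values is None else np.atleast_1d(np.asarray(s_values, float))
    u = np.asarray(fit.grid.u(s), dtype=float)
    sl = fit.basis.covariate_slice(covariate)
    b = fit.cox.coefficients[sl]
    cov = (fit.cox.robust_covariance if robust else fit.cox.model_covariance)[sl, sl]
    c = u[:, None] ** np.arange(len(b))[None, :]
    g = c @ b
    v = np.einsum("ij,jk,ik->i", c, cov, c)
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(v)
    return DynamicHR(
        covariate=covariate,
        landmark_times=s,
        hr=np.exp(g),
        ci_lower=np.exp(g - half),
        ci_upper=np.exp(g + half),
    )


def hazard_ratio_curve(
    coefficients: tuple[float, ...], s, s0: float = 0.0, sL: float = 10.0
) -> np.ndarray | float:
    """Evaluate HR(s) = exp(sum_k b_k * u^k), u = (s - s0)/(sL - s0).

    Convenience for working with published polynomial log-HR coefficients
    without a fitted model object.
    """
    u = (np.asarray(s, dtype=float) - s0) / (sL - s0)
    g = sum(b * u**k for k, b in enumerate(coefficients))
    out = np.exp(g)
    return float(out) if np.ndim(s) == 0 else out


class LandmarkSuperModel(BaseEstimator):
    """Dynamic Cox prediction by landmarking, as an sklearn-style estimator.

    Parameters
    ----------
    s0, s_max, spacing : landmark grid, in years (default: 41 points every
        3 months on [0, 10]).
    window : prediction window w in years (default 5).
    basis : :class:`BasisSpec`; ``None`` uses the renal-study default
        structure.
    covariate_specs : scaling/coding conventions; ``None`` uses the defaults.
    robust : use the cluster-robust (by subject) covariance for intervals.

    Fitted attributes
    -----------------
    fit_ : :class:`SuperModelFit`  —  coefficients, covariance, baseline.
    stacked_ : the super-dataset R the model was fitted on.
    coef_, coef_names_ : fitted coefficient vector and design column names.
    """

    def __init__(
        self,
        s0: float = 0.0,
        s_max: float = 10.0,
        spacing: float = 0.25,
        window: float = 5.0,
        basis: BasisSpec | None = None,
        covariate_specs: list[CovariateSpec] | None = None,
        robust: bool = True,
    ):
        self.s0 = s0
        self.s_max = s_max
        self.spacing = spacing
        self.window = window
        self.basis = basis
        self.covariate_specs = covariate_specs
        self.robust = robust

    def _specs(self) -> list[CovariateSpec]:
        return self.covariate_specs if self.covariate_specs is not None else default_covariate_specs()

    def _basis(self) -> BasisSpec:
        return self.basis if self.basis is not None else BasisSpec()

    def fit(self, cohort: pd.DataFrame, measurements: pd.DataFrame):
        """Scale, stack and fit; ``cohort``/``measurements`` are raw tables."""
        cohort = validate_cohort(cohort)
        measurements = validate_longitudinal(measurements, cohort=cohort)
        specs = self._specs()
        basis = self._basis()
        grid = make_grid(self.s0, self.s_max, self.spacing, self.window)
        scaled_cohort = apply_scaling(cohort, specs)
        scaled_long = apply_scaling(measurements, specs)
        biomarkers = [c for c in basis.covariates if c in BIOMARKERS]
        baseline_covs = [c for c in basis.covariates if c not in BIOMARKERS]
        stacked = stack(
            scaled_cohort,
            scaled_long,
            grid,
            biomarkers=biomarkers,
            baseline_covariates=baseline_covs,
        )
        self.grid_ = grid
        self.stacked_ = stacked
        self.fit_ = fit_supermodel(stacked, basis)
        self.coef_ = self.fit_.cox.coefficients
        self.coef_names_ = self.fit_.cox.design_column_names
        self.baseline_hazard_ = self.fit_.baseline
        return self

    # -- prediction ---------------------------------------------------------

    def predict_conditional_survival(self, z, s_l: float, w: float | None = None):
        """S(s_l + w | s_l, Z) for covariates ``z`` already on the model scale."""
        return predict_dynamic_survival(self.fit_, z, s_l, w)

    def predict_at_landmark(
        self,
        cohort: pd.DataFrame,
        measurements: pd.DataFrame,
        s_l: float,
        w: float | None = None,
    ) -> pd.DataFrame:
        """w-year conditional survival for every at-risk subject at ``s_l``.

        Raw tables in; a frame ``id, survival`` out (subjects with
        unresolvable biomarkers at ``s_l`` are omitted).
        """
        specs = self._specs()
        basis = self._basis()
        scaled_cohort = apply_scaling(validate_cohort(cohort), specs)
        scaled_long = apply_scaling(
            validate_longitudinal(measurements, cohort=cohort), specs
        )
        z = _covariates_at_landmark(scaled_cohort, scaled_long, s_l, basis)
        if len(z) == 0:
            return pd.DataFrame({"id": [], "survival": []})
        surv = predict_dynamic_survival(self.fit_, z, s_l, w)
        return pd.DataFrame({"id": z["id"].to_numpy(), "survival": np.atleast_1d(surv)})

    def dynamic_hr(self, covariate: str, s_values=None, alpha: float = 0.05) -> DynamicHR:
        return dynamic_hr(self.fit_, covariate, s_values, robust=self.robust, alpha=alpha)

    def individual_trajectory(
        self,
        measurements: pd.DataFrame,
        baseline: dict | pd.Series,
        time_years: float | None = None,
        w: float | None = None,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-landmark conditional survival for one subject (Fig-3 style).

        Parameters
        ----------
        measurements : the subject's raw visit table (id column optional).
        baseline : the subject's raw baseline covariates (age, sex, weight).
        time_years : observed survival/censoring time, if known; landmarks at
            or after it are skipped (the subject is no longer at risk).

        Returns
        -------
        trajectory : frame ``landmark, survival`` — the w-year conditional
            survival at each landmark where covariates resolve.
        curves : frame ``landmark, t, survival`` — the within-window
            "real-time" survival curve exp(-(H0(t) - H0(s_l)) e^lp), starting
            at 1 at each window's origin.
        """
        specs = self._specs()
        basis = self._basis()
        w = self.grid_.w if w is None else w
        meas = measurements.copy()
        if "id" not in meas.columns:
            meas["id"] = 0
        meas = meas.sort_values(["id", "obstime"], kind="mergesort")
        meas = apply_scaling(meas, specs)
        base = apply_scaling(pd.DataFrame([dict(baseline)]), specs).iloc[0]
        biomarkers = [c for c in basis.covariates if c in BIOMARKERS]
        rows, curve_rows = [], []
        for s_l in self.grid_.points:
            if time_years is not None and time_years <= s_l:
                break
            z = {c: base[c] for c in basis.covariates if c not in BIOMARKERS}
            locf = _locf_at(meas, float(s_l), biomarkers)
            if len(locf) == 0 or locf[biomarkers].isna().any(axis=None):
                continue
            for c in biomarkers:
                z[c] = float(locf.iloc[0][c])
            surv = predict_dynamic_survival(self.fit_, {k: [v] for k, v in z.items()}, float(s_l), w)
            rows.append({"landmark": float(s_l), "survival": float(surv)})
            lp = float(
                self.fit_.linear_predictor({k: [v] for k, v in z.items()}, float(s_l))[0]
            )
            bh = self.fit_.baseline
            in_window = (bh.event_times > s_l) & (bh.event_times <= s_l + w)
            t_in = bh.event_times[in_window]
            cum = np.cumsum(bh.increments[in_window])
            curve_rows.append({"landmark": float(s_l), "t": float(s_l), "survival": 1.0})
            for t, c_ in zip(t_in, cum):
                curve_rows.append(
                    {"landmark": float(s_l), "t": float(t), "survival": float(np.exp(-c_ * np.exp(lp)))}
                )
        if not rows:
            return (
                pd.DataFrame({"landmark": [], "survival": []}),
                pd.DataFrame({"landmark": [], "t": [], "survival": []}),
            )
        return pd.DataFrame(rows), pd.DataFrame(curve_rows)

    def coefficient_table(self) -> pd.DataFrame:
        """Table-style report: per basis term, coefficient, SEs and p-values."""
        fit = self.fit_.cox
        tab = pd.DataFrame(
            {
                "term": fit.design_column_names,
                "coef": fit.coefficients,
                "se_model": fit.model_se,
                "se_robust": fit.robust_se,
                "p_model": fit.p_values(robust=False),
                "p_robust": fit.p_values(robust=True),
            }
        )
        tab["covariate"] = [t.split(":")[0] for t in tab["term"]]
        return tab

    def joint_wald_tests(self, robust: bool = True) -> pd.DataFrame:
        """Per-covariate joint Wald chi-square test over all its basis terms."""
        fit = self.fit_.cox
        cov = fit.robust_covariance if robust else fit.model_covariance
        rows = []
        for name in self._basis().degrees:
            sl = self._basis().covariate_slice(name)
            b = fit.coefficients[sl]
            block = cov[sl, sl]
            chi2 = float(b @ np.linalg.solve(block, b))
            df = len(b)
            rows.append(
                {"covariate": name, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
            )
        return pd.DataFrame(rows)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        f = self.fit_
        return {
            "grid": {"s0": f.grid.s0, "sL": f.grid.sL, "spacing": f.grid.spacing, "w": f.grid.w},
            "basis": {"degrees": dict(f.basis.degrees), "theta_degree": f.basis.theta_degree},
            "coefficients": f.cox.coefficients.tolist(),
            "column_names": f.cox.design_column_names,
            "model_covariance": f.cox.model_covariance.tolist(),
            "robust_covariance": f.cox.robust_covariance.tolist(),
            "log_partial_likelihood": f.cox.log_partial_likelihood,
            "baseline_event_times": f.baseline.event_times.tolist(),
            "baseline_increments": f.baseline.increments.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSuperModel":
        g = d["grid"]
        model = cls(s0=g["s0"], s_max=g["sL"], spacing=g["spacing"], window=g["w"],
                    basis=BasisSpec(degrees=dict(d["basis"]["degrees"]),
                                    theta_degree=d["basis"]["theta_degree"]))
        grid = make_grid(g["s0"], g["sL"], g["spacing"], g["w"])
        cox = CoxFit(
            coefficients=np.asarray(d["coefficients"], float),
            model_covariance=np.asarray(d["model_covariance"], float),
            robust_covariance=np.asarray(d["robust_covariance"], float),
            log_partial_likelihood=d["log_partial_likelihood"],
            n_iterations=0,
            final_gradient_norm=0.0,
            design_column_names=list(d["column_names"]),
        )
        baseline = BaselineHazard(
            event_times=np.asarray(d["baseline_event_times"], float),
            increments=np.asarray(d["baseline_increments"], float),
        )
        model.grid_ = grid
        model.fit_ = SuperModelFit(basis=model._basis(), cox=cox, baseline=baseline, grid=grid)
        model.coef_ = cox.coefficients
        model.coef_names_ = cox.design_column_names
        model.baseline_hazard_ = baseline
        return model


def _covariates_at_landmark(
    scaled_cohort: pd.DataFrame,
    scaled_long: pd.DataFrame,
    s_l: float,
    basis: BasisSpec,
) -> pd.DataFrame:
    """At-risk subjects' scaled covariates at s_l (LOCF; unresolvable dropped)."""
    biomarkers = [c for c in basis.covariates if c in BIOMARKERS]
    baseline_covs = [c for c in basis.covariates if c not in BIOMARKERS]
    at_risk = scaled_cohort[scaled_cohort["time_years"] > s_l]
    out = at_risk[["id", "time_years", "event"] + baseline_covs].copy()
    if biomarkers:
        locf = _locf_at(scaled_long, s_l, biomarkers)
        out = out.merge(locf, on="id", how="left")
        out = out[out[biomarkers].notna().all(axis=1)]
    return out.reset_index(drop=True)


class StaticCoxModel(BaseEstimator):
    """Baseline-only Cox comparator: six covariates frozen at transplantation.

    Fits a plain proportional-hazards model on the baseline values (age, sex,
    weight and the time-0 biomarker measurements) and predicts conditional
    survival as S(s + w)/S(s) with the fixed baseline covariates.
    """

    def __init__(self, covariates: tuple = ("age", "sex", "weight", "hematocrit",
                                            "proteinuria", "gfr"),
                 covariate_specs: list[CovariateSpec] | None = None,
                 robust: bool = False):
        self.covariates = covariates
        self.covariate_specs = covariate_specs
        self.robust = robust

    def _specs(self):
        return self.covariate_specs if self.covariate_specs is not None else default_covariate_specs()

    def fit(self, cohort: pd.DataFrame, measurements: pd.DataFrame | None = None):
        cohort = validate_cohort(cohort)
        specs = self._specs()
        scaled = apply_scaling(cohort, specs)
        covs = list(self.covariates)
        biomarkers = [c for c in covs if c in BIOMARKERS]
        if biomarkers:
            if measurements is None:
                raise ValueError("baseline biomarker covariates need the longitudinal table")
            scaled_long = apply_scaling(
                validate_longitudinal(measurements, cohort=cohort), specs
            )
            baseline_vals = _locf_at(scaled_long, 0.0, biomarkers)
            scaled = scaled.merge(baseline_vals, on="id", how="left")
            ok = scaled[biomarkers].notna().all(axis=1)
            n_dropped = int((~ok).sum())
            if n_dropped:
                logger.info("static fit: dropped %d subject(s) without baseline biomarkers", n_dropped)
            scaled = scaled[ok]
        design = scaled[covs].to_numpy(float)
        times = scaled["time_years"].to_numpy(float)
        status = scaled["event"].to_numpy(int)
        fit = cox_engine.fit_partial_likelihood(
            design, np.zeros(len(times)), times, status,
            cluster_ids=scaled["id"].to_numpy() if self.robust else None,
            column_names=covs,
        )
        self.cox_ = fit
        self.coef_ = fit.coefficients
        self.coef_names_ = covs
        self.baseline_hazard_ = cox_engine.breslow_baseline(
            np.zeros(len(times)), times, status, design @ fit.coefficients
        )
        self.training_covariates_ = scaled[["id"] + covs].reset_index(drop=True)
        return self

    def predict_conditional_survival(self, z0, s_l: float, w: float) -> float | np.ndarray:
        """S(s_l + w)/S(s_l) for fixed baseline covariates z0 (model scale)."""
        if isinstance(z0, (dict, pd.Series)):
            z0 = pd.DataFrame({k: np.atleast_1d(v) for k, v in dict(z0).items()})
        lp = z0[list(self.coef_names_)].to_numpy(float) @ self.coef_
        h = self.baseline_hazard_.window_hazard(s_l, s_l + w)
        out = np.exp(-h * np.exp(lp))
        return float(out[0]) if out.size == 1 else out

    def predict_at_landmark(
        self,
        cohort: pd.DataFrame,
        measurements: pd.DataFrame,
        s_l: float,
        w: float,
    ) -> pd.DataFrame:
        """Conditional w-year survival at s_l for at-risk subjects (baseline z)."""
        specs = self._specs()
        scaled = apply_scaling(validate_cohort(cohort), specs)
        covs = list(self.covariates)
        biomarkers = [c for c in covs if c in BIOMARKERS]
        if biomarkers:
            scaled_long = apply_scaling(
                validate_longitudinal(measurements, cohort=cohort), specs
            )
            baseline_vals = _locf_at(scaled_long, 0.0, biomarkers)
            scaled = scaled.merge(baseline_vals, on="id", how="left")
            scaled = scaled[scaled[biomarkers].notna().all(axis=1)]
        at_risk = scaled[scaled["time_years"] > s_l]
        if len(at_risk) == 0:
            return pd.DataFrame({"id": [], "survival": []})
        surv = self.predict_conditional_survival(at_risk[covs], s_l, w)
        return pd.DataFrame({"id": at_risk["id"].to_numpy(), "survival": np.atleast_1d(surv)})


def fit_static(
    cohort: pd.DataFrame,
    measurements: pd.DataFrame | None = None,
    covariates: tuple = ("age", "sex", "weight", "hematocrit", "proteinuria", "gfr"),
) -> StaticCoxModel:
    """Fit the static baseline Cox comparator (thin wrapper)."""
    return StaticCoxModel(covariates=covariates).fit(cohort, measurements)


def predict_static_conditional(model: StaticCoxModel, z0, s_l: float, w: float):
    """Conditional survival from a fitted static model (thin wrapper)."""
    return model.predict_conditional_survival(z0, s_l, w)
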