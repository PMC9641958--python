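import numpy as np
import pandas as pd
import pytest

from landmarkcox import (
    BasisSpec,
    LandmarkSuperModel,
    SimulationParams,
    StaticCoxModel,
    fit_partial_likelihood,
    fit_supermodel,
    make_grid,
    simulate_cohort,
    stack,
)
from landmarkcox.cox_engine import breslow_baseline
from landmarkcox.data_model import apply_scaling, default_covariate_specs
from landmarkcox.model import (
    SuperModelFit,
    dynamic_hr,
    expand_basis,
    hazard_ratio_curve,
    predict_dynamic_survival,
)


class TestExpandBasis:
    grid = make_grid(0, 10, 0.25, 5)

    def test_degree_one_column(self):
        spec = BasisSpec(degrees={"x": 1}, theta_degree=0)
        row = expand_basis({"x": 1.0}, 4.0, self.grid, spec)
        assert row.tolist() == [[1.0, 0.4]]

    def test_degree_two_columns(self):
        spec = BasisSpec(degrees={"x": 2}, theta_degree=0)
        row = expand_basis({"x": 2.0}, 5.0, self.grid, spec)
        assert np.allclose(row, [[2.0, 1.0, 0.5]])

    def test_interactions_vanish_at_first_landmark(self):
        spec = BasisSpec(degrees={"x": 2}, theta_degree=2)
        row = expand_basis({"x": 3.0}, 0.0, self.grid, spec)
        assert np.allclose(row, [[3.0, 0.0, 0.0, 0.0, 0.0]])

    def test_missing_covariate_raises(self):
        spec = BasisSpec(degrees={"x": 1})
        with pytest.raises(KeyError, match="x"):
            expand_basis({"y": 1.0}, 0.0, self.grid, spec)

    def test_column_count_and_names(self):
        spec = BasisSpec()  # default renal-study structure
        assert spec.n_columns == 11
        assert spec.column_names == [
            "age", "weight", "hematocrit", "hematocrit:u", "gfr", "gfr:u",
            "proteinuria", "proteinuria:u", "proteinuria:u^2",
            "theta:u", "theta:u^2",
        ]

    def test_degree_bounds_enforced(self):
        with pytest.raises(ValueError):
            BasisSpec(degrees={"x": 3})


@pytest.fixture(scope="module")
def toy_fit():
    """Super-model wrapper around the 3-subject closed-form Cox fit."""
    design = np.array([[0.0], [1.0], [0.0]])
    entry = np.zeros(3)
    exit_ = np.array([1.0, 2.0, 3.0])
    status = np.array([1, 1, 0])
    cox = fit_partial_likelihood(design, entry, exit_, status, column_names=["x"])
    baseline = breslow_baseline(entry, exit_, status, design @ cox.coefficients)
    grid = make_grid(0, 10, 0.25, 5)
    spec = BasisSpec(degrees={"x": 0}, theta_degree=0)
    return SuperModelFit(basis=spec, cox=cox, baseline=baseline, grid=grid)


class TestPredictDynamicSurvival:
    def test_zero_window_is_certainty(self, toy_fit):
        assert predict_dynamic_survival(toy_fit, {"x": 0.0}, 0.0, w=0.0) == 1.0

    def test_hand_summed_breslow_increments(self, toy_fit):
        s = predict_dynamic_survival(toy_fit, {"x": 0.0}, 0.0, w=3.0)
        root2 = np.sqrt(2)
        assert s == pytest.approx(np.exp(-(1 / (2 + root2) + 1 / (1 + root2))), abs=1e-9)
        assert s == pytest.approx(0.49306, abs=1e-5)

    def test_single_increment_closed_form(self, toy_fit):
        # only the t=1 increment falls inside (0, 1.5]
        s = predict_dynamic_survival(toy_fit, {"x": 0.0}, 0.0, w=1.5)
        assert s == pytest.approx(np.exp(-1 / (2 + np.sqrt(2))), abs=1e-9)

    def test_monotone_in_window_and_bounded(self, toy_fit):
        vals = [predict_dynamic_survival(toy_fit, {"x": 0.5}, 0.0, w=w)
                for w in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_outside_grid_rejected(self, toy_fit):
        with pytest.raises(ValueError, match="outside"):
            predict_dynamic_survival(toy_fit, {"x": 0.0}, 12.0)


class TestDynamicHR:
    def test_published_hematocrit_value_at_baseline(self):
        # exp(0.256) with the linear-in-u log-HR evaluated at s = 0
        assert hazard_ratio_curve((0.256, -1.498), 0.0) == pytest.approx(1.292, abs=1e-3)

    def test_null_coefficients_give_unit_hr(self):
        assert np.allclose(hazard_ratio_curve((0.0, 0.0), np.linspace(0, 10, 11)), 1.0)

    def test_log2_slope_doubles_at_u_one(self):
        assert hazard_ratio_curve((0.0, np.log(2)), 10.0) == pytest.approx(2.0)

    def test_fitted_hr_and_ci(self, fitted_dynamic):
        hr = fitted_dynamic.dynamic_hr("hematocrit")
        assert np.all(hr.hr > 0)
        assert np.all(hr.ci_lower <= hr.hr) and np.all(hr.hr <= hr.ci_upper)
        sl = fitted_dynamic.fit_.basis.covariate_slice("hematocrit")
        b = fitted_dynamic.coef_[sl]
        assert hr.hr[0] == pytest.approx(np.exp(b[0]))

    def test_unknown_covariate_rejected(self, fitted_dynamic):
        with pytest.raises(KeyError):
            fitted_dynamic.dynamic_hr("sex")


def test_supermodel_collapses_to_plain_cox_at_single_landmark(small_cohort):
    """Restricted to s_0 = 0 with constant effects and no theta terms, the
    super-model is an ordinary baseline Cox fit on R_0."""
    cohort, long = small_cohort
    specs = default_covariate_specs()
    scaled_c = apply_scaling(cohort, specs)
    scaled_l = apply_scaling(long, specs)
    grid = make_grid(0, 1e-9, 1e-9, 5)  # a single landmark at ~0
    spec = BasisSpec(degrees={"age": 0, "weight": 0, "gfr": 0}, theta_degree=0)
    stacked = stack(scaled_c, scaled_l, grid, biomarkers=["gfr"],
                    baseline_covariates=["age", "weight"])
    sm = fit_supermodel(stacked, spec)
    rows = stacked.rows
    plain = fit_partial_likelihood(
        rows[["age", "weight", "gfr"]].to_numpy(float),
        rows["entry"].to_numpy(float), rows["exit"].to_numpy(float),
        rows["status"].to_numpy(int),
    )
    assert sm.cox.coefficients == pytest.approx(plain.coefficients, abs=1e-10)


def test_recovers_decaying_biomarker_effect():
    """One replicate of the recovery design: beta_htc(u) = 0.3 - 1.5u with a
    short window keeps the landmark estimand close to the generating truth."""
    params = SimulationParams(
        n_subjects=1500,
        true_effects={"hematocrit": (0.3, -1.5)},
        baseline_hazard_rate=0.05,
        seed=31,
        censor_min_years=0.0,
    )
    cohort, long = simulate_cohort(params)
    model = LandmarkSuperModel(
        window=1.0, basis=BasisSpec(degrees={"hematocrit": 1}, theta_degree=2)
    ).fit(cohort, long)
    b0, b1 = model.coef_[0], model.coef_[1]
    se0, se1 = model.fit_.cox.robust_se[:2]
    assert abs(b0 - 0.3) < 3 * se0
    assert abs(b1 + 1.5) < 3 * se1


class TestIndividualTrajectory:
    def test_windows_start_at_certainty(self, fitted_dynamic, small_cohort):
        cohort, long = small_cohort
        sid = cohort.loc[cohort.time_years.idxmax(), "id"]
        base = cohort[cohort.id == sid].iloc[0]
        traj, curves = fitted_dynamic.individual_trajectory(
            long[long.id == sid],
            {"age": base.age, "sex": base.sex, "weight": base.weight},
            time_years=base.time_years,
        )
        assert len(traj) > 0
        starts = curves.groupby("landmark").first()
        assert (starts["survival"] == 1.0).all()
        assert ((traj.survival >= 0) & (traj.survival <= 1)).all()
        # within each window the real-time curve is non-increasing
        for _, g in curves.groupby("landmark"):
            assert (np.diff(g["survival"]) <= 1e-12).all()

    def test_constant_covariates_vary_only_through_time_terms(self, fitted_dynamic):
        long = pd.DataFrame(
            {"id": 0, "obstime": [0.0], "hematocrit": [29.5],
             "proteinuria": [0.5], "gfr": [50.0]}
        )
        traj, _ = fitted_dynamic.individual_trajectory(
            long, {"age": 45.0, "sex": "male", "weight": 70.0}
        )
        # covariates never change, so predictions at two landmarks differ only
        # via theta(u), the u-interactions and the baseline-hazard window
        assert len(traj) == len(fitted_dynamic.grid_.points)
        assert traj.survival.between(0, 1).all()

    def test_never_at_risk_gives_empty(self, fitted_dynamic):
        long = pd.DataFrame(
            {"id": 0, "obstime": [0.0], "hematocrit": [29.5],
             "proteinuria": [0.5], "gfr": [50.0]}
        )
        traj, curves = fitted_dynamic.individual_trajectory(
            long, {"age": 45.0, "sex": "male", "weight": 70.0}, time_years=0.0
        )
        assert len(traj) == 0 and len(curves) == 0


class TestStaticModel:
    def test_conditional_prediction_at_baseline_is_plain_survival(self, fitted_static):
        z0 = fitted_static.training_covariates_.iloc[[0]]
        s = fitted_static.predict_conditional_survival(z0, 0.0, 5.0)
        lp = z0[list(fitted_static.coef_names_)].to_numpy(float) @ fitted_static.coef_
        h = fitted_static.baseline_hazard_.cumulative_at(5.0)
        assert s == pytest.approx(float(np.exp(-h * np.exp(lp[0]))))

    def test_zero_lp_prediction_is_baseline_hazard_only(self, fitted_static):
        z0 = {name: 0.0 for name in fitted_static.coef_names_}
        s = fitted_static.predict_conditional_survival(z0, 2.0, 5.0)
        h = fitted_static.baseline_hazard_.window_hazard(2.0, 7.0)
        assert s == pytest.approx(float(np.exp(-h)))

    def test_non_increasing_in_window(self, fitted_static):
        z0 = fitted_static.training_covariates_.iloc[[3]]
        vals = [
            float(fitted_static.predict_conditional_survival(z0, 1.0, w))
            for w in (0.5, 1.0, 2.0, 5.0, 10.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_sklearn_params_round_trip():
    model = LandmarkSuperModel(spacing=0.5, window=10.0)
    params = model.get_params()
    assert params["spacing"] == 0.5 and params["window"] == 10.0
    clone = LandmarkSuperModel(**params)
    assert clone.get_params() == params


def test_model_serialisation_round_trip(fitted_dynamic, small_cohort):
    cohort, long = small_cohort
    d = fitted_dynamic.to_dict()
    back = LandmarkSuperModel.from_dict(d)
    assert np.allclose(back.coef_, fitted_dynamic.coef_)
    p1 = fitted_dynamic.predict_at_landmark(cohort, long, 2.0)
    p2 = back.predict_at_landmark(cohort, long, 2.0)
    pd.testing.assert_frame_equal(p1, p2)
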