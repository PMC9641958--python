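import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landmarkcox import (
    CVPlan,
    SimulationParams,
    brier_ipcw,
    evaluate_per_landmark,
    harrell_c,
    make_grid,
    monte_carlo_cv,
    simulate_cohort,
)


class TestHarrellC:
    def test_pair_enumeration_example(self):
        # usable pairs (1,2),(1,3),(2,3); the last is discordant
        c = harrell_c([0.9, 0.5, 0.7], [1, 2, 3], [1, 1, 1])
        assert c == pytest.approx(2 / 3)

    def test_perfect_ordering(self):
        assert harrell_c([3.0, 2.0, 1.0], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_all_tied_risks_are_chance(self):
        assert harrell_c([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [1, 1, 1, 0]) == 0.5

    def test_censored_smaller_time_not_usable(self):
        # (1, 2) unusable because the earlier subject is censored
        c = harrell_c([0.2, 0.9, 0.5], [1, 2, 3], [0, 1, 1])
        assert c == pytest.approx(1.0)  # only (2,3) usable, concordant

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([0.1, 0.2], [1.0, 2.0], [0, 1])
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([0.1, 0.2], [2.0, 2.0], [1, 1])  # tied times

    def test_matches_scikit_survival(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(8)
        n = 150
        risk = rng.normal(size=n)
        times = rng.exponential(size=n) * np.exp(-0.7 * risk) + 1e-6
        status = rng.random(n) < 0.7
        ours = harrell_c(risk, times, status.astype(int))
        theirs = sksurv_metrics.concordance_index_censored(status, times, risk)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_complement_property_for_tie_free_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        risk = rng.permutation(n).astype(float)
        times = np.sort(rng.exponential(size=n)) + np.arange(n) * 1e-6
        status = (rng.random(n) < 0.7).astype(int)
        status[0] = 1  # guarantee a usable pair
        assert harrell_c(risk, times, status) + harrell_c(-risk, times, status) == pytest.approx(1.0)


class TestBrierIPCW:
    def test_perfect_predictions_score_zero(self):
        times = np.array([1.0, 2.0, 8.0, 9.0])
        status = np.array([1, 1, 0, 0])
        pred = np.array([0.0, 0.0, 1.0, 1.0])
        assert brier_ipcw(pred, times, status, horizon=5.0) == 0.0

    def test_uninformative_half_predictions(self):
        # no censoring, 2 events before the horizon: mean of four (0.5)^2
        times = np.array([1.0, 2.0, 8.0, 9.0])
        status = np.array([1, 1, 1, 1])
        pred = np.full(4, 0.5)
        assert brier_ipcw(pred, times, status, horizon=5.0) == pytest.approx(0.25)

    def test_event_rate_prediction_gives_bernoulli_variance(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(size=400) + 1e-9
        status = np.ones(400, int)
        horizon = float(np.median(times))
        p = float(np.mean(times <= horizon))
        score = brier_ipcw(np.full(400, 1 - p), times, status, horizon)
        assert score == pytest.approx(p * (1 - p), abs=1e-12)

    def test_no_censoring_equals_plain_mse(self):
        rng = np.random.default_rng(6)
        n = 100
        times = rng.exponential(size=n) + 1e-9
        status = np.ones(n, int)
        pred = rng.random(n)
        horizon = 1.0
        outcome = (times <= horizon).astype(float)
        mse = np.mean((outcome - (1 - pred)) ** 2)
        assert brier_ipcw(pred, times, status, horizon) == pytest.approx(mse, abs=1e-12)

    def test_matches_scikit_survival_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(9)
        n = 200
        times = rng.exponential(2.0, size=n) + 1e-9
        status = rng.random(n) < 0.6
        pred = np.clip(rng.random(n), 0.01, 0.99)
        horizon = 1.5
        y = np.array(list(zip(status, times)), dtype=[("e", bool), ("t", float)])
        _, theirs = sksurv_metrics.brier_score(y, y, pred[:, None], [horizon])
        ours = brier_ipcw(pred, times, status.astype(int), horizon)
        assert ours == pytest.approx(theirs[0], abs=1e-10)

    def test_inestimable_weights_raise(self):
        # everyone censored before the horizon: G hits 0, weights undefined
        times = np.array([0.5, 0.6, 0.7])
        status = np.array([0, 0, 0])
        with pytest.raises(ValueError, match="inestimable"):
            brier_ipcw(np.array([0.5, 0.5, 0.5]), times, status, horizon=1.0)

    def test_predictions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            brier_ipcw([1.2], [1.0], [1], 2.0)


class TestEvaluatePerLandmark:
    def test_perfect_prediction_fixture_has_zero_brier(self):
        class Oracle:
            """Predicts each subject's window outcome exactly."""

            def __init__(self, cohort):
                self.cohort = cohort

            def predict_at_landmark(self, cohort, measurements, s_l, w):
                sub = cohort[cohort["time_years"] > s_l]
                surv = (
                    ~((sub["event"] == 1) & (sub["time_years"] <= s_l + w))
                ).astype(float)
                return pd.DataFrame({"id": sub["id"], "survival": surv})

        cohort = pd.DataFrame(
            {
                "id": range(1, 9),
                "time_years": [0.5, 1.5, 2.5, 4.0, 6.0, 7.0, 8.0, 9.0],
                "event": [1, 1, 0, 1, 1, 0, 1, 0],
                "age": 40.0, "sex": "male", "weight": 70.0,
            }
        )
        grid = make_grid(0, 2, 1.0, 5)
        ccurve, bcurve = evaluate_per_landmark(
            Oracle(cohort), cohort, pd.DataFrame(), grid, label="oracle"
        )
        assert np.nanmax(bcurve.values) == 0.0
        # binary risks tie within the event group, so C < 1 is expected;
        # it must still be far above chance
        assert np.nanmin(ccurve.values) > 0.8

    def test_dynamic_beats_static_with_time_varying_effects(self, small_cohort, fitted_dynamic, fitted_static):
        """In-sample qualitative check on default synthetic data; the honest
        held-out comparison lives in the acceptance suite."""
        cohort, long = small_cohort
        grid = make_grid(0, 10, 0.5, 5)
        c_dyn, _ = evaluate_per_landmark(fitted_dynamic, cohort, long, grid)
        c_sta, _ = evaluate_per_landmark(fitted_static, cohort, long, grid)
        assert c_dyn.mean > c_sta.mean

    def test_metric_curve_tidy_frame(self, small_cohort, fitted_static):
        cohort, long = small_cohort
        grid = make_grid(0, 10, 2.0, 5)
        ccurve, bcurve = evaluate_per_landmark(fitted_static, cohort, long, grid)
        frame = ccurve.to_frame()
        assert list(frame.columns) == ["model", "metric", "window", "landmark", "value"]
        assert (frame["model"] == "static").all()
        assert len(frame) == len(grid.points)
        assert 0.0 <= ccurve.mean <= 1.0 and 0.0 <= bcurve.mean <= 1.0


@pytest.fixture(scope="module")
def tiny_sim():
    return simulate_cohort(SimulationParams(n_subjects=160, seed=2))


class TestMonteCarloCV:
    def test_deterministic_given_seed(self, tiny_sim):
        cohort, long = tiny_sim
        grid = make_grid(0, 10, 2.0, 5)
        plan = CVPlan(iterations=2, seed=5)
        out1 = monte_carlo_cv(cohort, long, grid, plan)
        out2 = monte_carlo_cv(cohort, long, grid, plan)
        pd.testing.assert_frame_equal(out1, out2)

    def test_summary_rows_average_landmark_rows(self, tiny_sim):
        cohort, long = tiny_sim
        grid = make_grid(0, 10, 2.0, 5)
        out = monte_carlo_cv(cohort, long, grid, CVPlan(iterations=2, seed=5))
        for (model, metric), grp in out.groupby(["model", "metric"]):
            per_lm = grp[grp.landmark.notna()]["value"]
            overall = grp[grp.landmark.isna()]["value"].iloc[0]
            assert overall == pytest.approx(per_lm.mean())

    def test_degenerate_split_rejected(self, tiny_sim):
        cohort, long = tiny_sim
        with pytest.raises(ValueError):
            CVPlan(iterations=1, train_fraction=1.0)
        with pytest.raises(ValueError):
            monte_carlo_cv(
                cohort.iloc[:3], long, make_grid(0, 10, 5.0, 5),
                CVPlan(iterations=1, train_fraction=0.9),
            )

    def test_too_many_unfittable_iterations_raise(self):
        # two subjects cannot support a 9-parameter training fit
        cohort, long = simulate_cohort(SimulationParams(n_subjects=4, seed=3))
        with pytest.raises(RuntimeError, match="unfittable"):
            monte_carlo_cv(
                cohort, long, make_grid(0, 10, 5.0, 5), CVPlan(iterations=2, seed=0)
            )
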