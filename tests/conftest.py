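import numpy as np
import pandas as pd
import pytest

from landmarkcox import (
    LandmarkSuperModel,
    SimulationParams,
    StaticCoxModel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_cox():
    """Three subjects, one binary covariate; the partial-likelihood score
    equation reduces to e^{2b} = 2, so the MLE is ln(2)/2."""
    design = np.array([[0.0], [1.0], [0.0]])
    entry = np.zeros(3)
    exit_ = np.array([1.0, 2.0, 3.0])
    status = np.array([1, 1, 0])
    return design, entry, exit_, status


@pytest.fixture(scope="session")
def toy_km():
    """Events at 1 and 2, censorings at 1.5 and 3: S(2) = (3/4)(1/2) = 0.375."""
    return np.array([1.0, 1.5, 2.0, 3.0]), np.array([1, 0, 1, 0])


@pytest.fixture(scope="session")
def small_cohort():
    """A default-parameter synthetic cohort small enough for fast tests."""
    cohort, long = simulate_cohort(SimulationParams(n_subjects=300, seed=11))
    return cohort, long


@pytest.fixture(scope="session")
def fitted_dynamic(small_cohort):
    cohort, long = small_cohort
    return LandmarkSuperModel(spacing=0.5).fit(cohort, long)


@pytest.fixture(scope="session")
def fitted_static(small_cohort):
    cohort, long = small_cohort
    return StaticCoxModel().fit(cohort, long)


@pytest.fixture()
def tiny_cohort_tables():
    """Hand-written raw tables: three subjects, a handful of visits."""
    cohort = pd.DataFrame(
        {
            "id": [1, 2, 3],
            "time_years": [1.0, 2.0, 3.0],
            "event": [1, 0, 1],
            "age": [41.6, 30.0, 55.0],
            "sex": ["male", "female", "male"],
            "weight": [63.81, 70.0, 58.0],
        }
    )
    long = pd.DataFrame(
        {
            "id": [1, 1, 2, 3, 3],
            "obstime": [0.0, 0.5, 0.0, 0.0, 2.0],
            "hematocrit": [29.5, 31.0, 28.0, 27.0, np.nan],
            "proteinuria": [2.4, 2.0, 1.0, 3.0, 3.5],
            "gfr": [8.9, 9.5, 10.0, 7.0, 6.5],
        }
    )
    return cohort, long
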