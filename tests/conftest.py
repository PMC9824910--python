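import numpy as np
import pandas as pd
import pytest

from glandmark import Cohort, build_landmark_dataset, simulate_cohort
from glandmark.simulate import SimulatorConfig


@pytest.fixture
def toy_cohort():
    """3 subjects, 2 visits each, a biomarker and a fixed covariate."""
    visits = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b", "c", "c"],
        "visit_time": [0.0, 1.0, 0.0, 2.0, 0.0, 1.5],
        "marker": [10.0, 8.0, 12.0, 9.0, 7.0, 6.5],
        "age": [60.0, 61.0, 55.0, 57.0, 70.0, 71.5],
    })
    outcomes = pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "followup_time": [4.0, 3.0, 5.0],
        "event": [1, 0, 1],
    })
    return Cohort(visits=visits, outcomes=outcomes,
                  covariate_names=["marker", "age"])


@pytest.fixture
def small_sim_cohort():
    """A modest simulated cohort shared by estimator tests."""
    cfg = SimulatorConfig(n_subjects=250, seed=7)
    cohort, _ = simulate_cohort(cfg)
    return cohort


@pytest.fixture
def small_landmark(small_sim_cohort):
    return build_landmark_dataset(small_sim_cohort)


@pytest.fixture
def eight_record_metrics():
    """Hand-computed IPCW fixture: censored validation records and the exact
    product-limit AUC (59/80) and Brier score (299/1200) at horizon 4.5."""
    frame = pd.DataFrame({
        "residual_time": [1, 2, 3, 4, 5, 6, 7, 8],
        "event": [1, 0, 1, 1, 0, 1, 0, 1],
        "prediction": [0.9, 0.3, 0.8, 0.2, 0.6, 0.7, 0.1, 0.4],
    })
    return frame, 4.5, 59.0 / 80.0, 299.0 / 1200.0
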