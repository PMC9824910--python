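import numpy as np
import pandas as pd
import pytest

from glandmark import (
    GLARisk,
    StaticCoxRisk,
    build_landmark_dataset,
    fit_weighted_cox,
    predict_risk_many,
    select_span,
    simulate_cohort,
    time_dependent_auc,
)
from glandmark.cohort import LandmarkDataset
from glandmark.simulate import SimulatorConfig, drifted_config


@pytest.fixture(scope="module")
def sim_cohort():
    cohort, _ = simulate_cohort(SimulatorConfig(n_subjects=300, seed=13))
    return cohort


@pytest.fixture(scope="module")
def sim_landmark(sim_cohort):
    return build_landmark_dataset(sim_cohort)


class TestStaticCoxRisk:
    def test_uses_one_row_per_subject(self, sim_cohort):
        est = StaticCoxRisk(covariates=["egfr", "age", "exposure"])
        est.fit(sim_cohort)
        assert est.n_subjects_ == sim_cohort.n_subjects

    def test_equals_full_span_gla_on_single_visit_cohort(self, sim_cohort):
        # keep only the baseline visit of every subject
        base = sim_cohort.visits[sim_cohort.visits.visit_time == 0]
        from glandmark.cohort import Cohort
        single = Cohort(visits=base.reset_index(drop=True),
                        outcomes=sim_cohort.outcomes,
                        covariate_names=sim_cohort.covariate_names)
        covs = ["egfr", "age", "exposure"]
        spm = StaticCoxRisk(covariates=covs).fit(single)
        # all visit times are 0, so span-based localization is degenerate;
        # a fixed bandwidth makes every weight equal instead
        gla = GLARisk(landmark_variables=("time",), kernel="uniform",
                      span=None, bandwidth=1.0, standardize=False,
                      covariates=covs,
                      adjust_landmark_linear=False, min_events=1).fit(single)
        queries = build_landmark_dataset(single).rows
        p_spm = spm.predict_risk(queries, 3.0)
        p_gla = gla.predict_risk(queries, 3.0)
        np.testing.assert_allclose(p_spm, p_gla, atol=1e-12)

    def test_null_covariates_give_chance_auc(self):
        # outcome generated independently of every covariate
        cfg = SimulatorConfig(n_subjects=500, seed=31, coef_landmark=0.0,
                              coef_funcs={"age": 0.0, "exposure": 0.0})
        cohort, _ = simulate_cohort(cfg)
        half = cohort.outcomes.subject_id[:250]
        rest = cohort.outcomes.subject_id[250:]
        est = StaticCoxRisk(covariates=["egfr", "age", "exposure"])
        est.fit(cohort.subset(half))
        assert np.abs(est.fit_.coefficients).max() < 0.05
        rows = build_landmark_dataset(cohort.subset(rest)).rows
        auc = time_dependent_auc(rows.residual_time, rows.event,
                                 est.predict_risk(rows, 3.0), 3.0)
        assert 0.42 < auc < 0.58


class TestGLARisk:
    def test_full_span_uniform_equals_pooled_cox(self, sim_cohort,
                                                 sim_landmark):
        covs = ["age", "exposure"]
        gla = GLARisk(landmark_variables=("egfr",), kernel="uniform",
                      span=1.0, covariates=covs,
                      adjust_landmark_linear=True).fit(sim_cohort)
        pooled = fit_weighted_cox(sim_landmark,
                                  covariate_subset=covs + ["egfr"])
        queries = sim_landmark.rows.iloc[::7]
        p_gla = gla.predict_risk(queries, 3.0)
        p_pooled = predict_risk_many(pooled, queries, 3.0)
        np.testing.assert_allclose(p_gla, p_pooled, atol=1e-12)
        # local coefficient on the landmark variable equals the pooled one
        fit0 = gla._local_fit(np.array([45.0]))
        assert fit0.coefficients["egfr"] == pytest.approx(
            pooled.coefficients["egfr"], abs=1e-10)

    def test_time_localization_reproduces_classical_la(self, sim_cohort,
                                                       sim_landmark):
        gla = GLARisk(landmark_variables=("time",), kernel="uniform",
                      span=1.0, covariates=["egfr", "age", "exposure"],
                      adjust_landmark_linear=False).fit(sim_cohort)
        # weights depend on |s - t_ij| only: a query at s=1.0 must weight
        # visits by their visit_time distance, regardless of covariates
        from glandmark.kernels import compute_weights, KernelSpec
        spec = KernelSpec(("time",), kernel="uniform", span=0.3,
                          standardize=False)
        wv = compute_weights(sim_landmark, spec, [1.0], min_events=1)
        d = np.abs(sim_landmark.rows.visit_time.to_numpy() - 1.0)
        h = wv.bandwidths[0]
        assert ((wv.weights > 0) == (d <= h)).all()
        # and the estimator predicts deterministically
        q = sim_landmark.rows.iloc[[3]]
        p1 = gla.predict_risk(q, 3.0)
        p2 = gla.predict_risk(q, 3.0)
        assert p1[0] == p2[0]

    def test_identical_queries_identical_predictions(self, sim_cohort,
                                                     sim_landmark):
        gla = GLARisk(landmark_variables=("egfr",), span=0.5,
                      covariates=["age", "exposure"]).fit(sim_cohort)
        q = sim_landmark.rows.iloc[[5, 5]]
        p = gla.predict_risk(q, 3.0)
        assert p[0] == p[1]

    def test_row_order_invariance(self, sim_cohort, sim_landmark):
        covs = ["age", "exposure"]
        gla1 = GLARisk(landmark_variables=("egfr",), span=0.4,
                       covariates=covs).fit(sim_landmark)
        shuffled = LandmarkDataset(
            rows=sim_landmark.rows.sample(frac=1.0, random_state=3)
                                  .reset_index(drop=True),
            covariate_names=sim_landmark.covariate_names)
        gla2 = GLARisk(landmark_variables=("egfr",), span=0.4,
                       covariates=covs).fit(shuffled)
        q = sim_landmark.rows.iloc[::13]
        np.testing.assert_allclose(gla1.predict_risk(q, 3.0),
                                   gla2.predict_risk(q, 3.0), atol=1e-9)

    def test_grid_mode_close_to_per_query(self, sim_cohort, sim_landmark):
        covs = ["age", "exposure"]
        exact = GLARisk(landmark_variables=("egfr",), span=0.4,
                        covariates=covs).fit(sim_cohort)
        grid = GLARisk(landmark_variables=("egfr",), span=0.4,
                       covariates=covs, grid_size=25).fit(sim_cohort)
        q = sim_landmark.rows.iloc[::5]
        p_exact = exact.predict_risk(q, 3.0)
        p_grid = grid.predict_risk(q, 3.0)
        assert np.max(np.abs(p_exact - p_grid)) < 0.05
        assert np.mean(np.abs(p_exact - p_grid)) < 0.01

    def test_sign_recovery_under_drift(self):
        cohort, _ = simulate_cohort(drifted_config(800, seed=17))
        gla = GLARisk(landmark_variables=("egfr",), span=0.2,
                      covariates=["exposure"],
                      adjust_landmark_linear=True).fit(cohort)
        lo = gla._local_fit(np.array([32.0])).coefficients["exposure"]
        hi = gla._local_fit(np.array([60.0])).coefficients["exposure"]
        assert lo > 0.3 and hi < -0.3

    def test_missing_time_anchor_warns_and_can_be_silenced(self, sim_cohort):
        with pytest.warns(UserWarning, match="timing"):
            GLARisk(landmark_variables=("egfr",), span=0.5,
                    covariates=["exposure"]).fit(sim_cohort)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("error")
            GLARisk(landmark_variables=("egfr",), span=0.5,
                    covariates=["exposure"],
                    warn_missing_time_anchor=False).fit(sim_cohort)

    def test_sklearn_param_interface(self):
        est = GLARisk(span=0.3)
        assert est.get_params()["span"] == 0.3
        est.set_params(span=0.7, kernel="uniform")
        assert est.get_params()["span"] == 0.7
        from sklearn.base import clone
        cl = clone(est)
        assert cl.get_params() == est.get_params()


class TestSelectSpan:
    def test_singleton_grid(self, sim_cohort):
        proto = GLARisk(landmark_variables=("egfr",),
                        covariates=["age", "exposure"], min_events=5)
        res = select_span(sim_cohort, proto, [1.0], horizon=3.0,
                          n_splits=1, n_boot=10, seed=2)
        assert res.selected_span == 1.0
        assert res.to_frame().selected.sum() == 1

    def test_drifted_prefers_small_span(self):
        cohort, _ = simulate_cohort(drifted_config(800, seed=23))
        proto = GLARisk(landmark_variables=("egfr",),
                        covariates=["age", "exposure"],
                        adjust_landmark_linear=True, grid_size=12,
                        min_events=5)
        res = select_span(cohort, proto, [0.2, 1.0], horizon=3.0,
                          n_splits=2, n_boot=30, seed=3)
        b = dict(zip(res.grid, res.brier))
        assert b[0.2] < b[1.0]
        assert res.selected_span == 0.2
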