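import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from glandmark import fit_weighted_cox, predict_risk
from glandmark.cox import StepFunction, LocalCoxFit
from glandmark.errors import CoxFitError

from oracles import (
    maximize_partial_loglik,
    naive_partial_loglik,
    random_survival_frame,
)


def _frame(times, events, X, names=None):
    names = names or [f"x{k}" for k in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["residual_time"] = times
    df["event"] = events
    return df, names


EIGHT_ROW = pd.DataFrame({
    # fixed small dataset exercising censoring and a tie at t=5
    "residual_time": [1.0, 2.0, 3.0, 3.5, 5.0, 5.0, 6.0, 8.0],
    "event":         [1,   0,   1,   1,   1,   1,   0,   1],
    "z1": [0.5, -1.2, -0.3, 1.8, -0.7, 0.9, 0.1, -1.5],
    "z2": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
})


class TestFitWeightedCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        # two groups with identical event/censoring patterns
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 0, 1, 1] * 2
        z = [0.0] * 4 + [1.0] * 4
        df, names = _frame(np.array(times), np.array(events),
                           np.array(z)[:, None])
        fit = fit_weighted_cox(df, covariate_subset=names)
        assert fit.converged
        assert fit.coefficients.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_eight_row_fixture_matches_brute_force_oracle(self):
        names = ["z1", "z2"]
        fit = fit_weighted_cox(EIGHT_ROW, covariate_subset=names)
        t = EIGHT_ROW["residual_time"].to_numpy()
        e = EIGHT_ROW["event"].to_numpy()
        X = EIGHT_ROW[names].to_numpy()
        beta_star = maximize_partial_loglik(t, e, X, np.ones(len(t)))
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_star,
                                   atol=1e-6)

    def test_duplication_with_halved_weights_is_invariant(self):
        names = ["z1", "z2"]
        fit1 = fit_weighted_cox(EIGHT_ROW, covariate_subset=names)
        doubled = pd.concat([EIGHT_ROW, EIGHT_ROW], ignore_index=True)
        w = np.full(len(doubled), 0.5)
        fit2 = fit_weighted_cox(doubled, weights=w, covariate_subset=names)
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients,
                                   atol=1e-9)
        np.testing.assert_allclose(fit1.baseline_cumhaz.values,
                                   fit2.baseline_cumhaz.values, atol=1e-9)
        np.testing.assert_allclose(fit1.baseline_cumhaz.knots,
                                   fit2.baseline_cumhaz.knots)

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_weight_scale_invariance(self, scale):
        names = ["z1", "z2"]
        base = fit_weighted_cox(EIGHT_ROW, covariate_subset=names)
        scaled = fit_weighted_cox(EIGHT_ROW,
                                  weights=np.full(len(EIGHT_ROW), scale),
                                  covariate_subset=names)
        np.testing.assert_allclose(base.coefficients, scaled.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(base.baseline_cumhaz.values,
                                   scaled.baseline_cumhaz.values, atol=1e-10)

    def test_zero_weight_rows_are_inert(self):
        names = ["z1", "z2"]
        junk = EIGHT_ROW.copy()
        junk["z1"] = 99.0
        junk["residual_time"] = 0.123
        stacked = pd.concat([EIGHT_ROW, junk], ignore_index=True)
        w = np.concatenate([np.ones(len(EIGHT_ROW)), np.zeros(len(junk))])
        fit = fit_weighted_cox(stacked, weights=w, covariate_subset=names)
        ref = fit_weighted_cox(EIGHT_ROW, covariate_subset=names)
        np.testing.assert_allclose(fit.coefficients, ref.coefficients,
                                   atol=1e-12)
        np.testing.assert_allclose(fit.baseline_cumhaz.values,
                                   ref.baseline_cumhaz.values, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_lifelines_and_score_vanishes(self, seed):
        rng = np.random.default_rng(seed)
        t, e, X = random_survival_frame(rng, n_rows=30)
        df, names = _frame(t, e, X)
        fit = fit_weighted_cox(df, covariate_subset=names)
        assert fit.converged and fit.score_norm < 1e-6
        cph = CoxPHFitter().fit(df[["residual_time", "event", *names]],
                                "residual_time", "event",
                                fit_options={"precision": 1e-10,
                                             "max_steps": 500})
        np.testing.assert_allclose(fit.coefficients.to_numpy(),
                                   cph.params_.to_numpy(), atol=1e-5)

    def test_tied_times_match_breslow_oracle(self):
        rng = np.random.default_rng(11)
        t, e, X = random_survival_frame(rng, n_rows=14, tie_prob=1.0)
        df, names = _frame(t, e, X)
        fit = fit_weighted_cox(df, covariate_subset=names)
        beta_star = maximize_partial_loglik(t, e, X, np.ones(len(t)))
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_star,
                                   atol=1e-6)
        # loglik agrees with the naive double-loop evaluation (centered)
        ll = naive_partial_loglik(fit.coefficients.to_numpy(), t, e,
                                  X - fit.covariate_center.to_numpy(),
                                  np.ones(len(t)))
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_no_events_raises(self):
        df, names = _frame(np.array([1.0, 2.0]), np.array([0, 0]),
                           np.zeros((2, 1)))
        with pytest.raises(CoxFitError, match="no events"):
            fit_weighted_cox(df, covariate_subset=names)

    def test_constant_covariate_dropped_with_warning(self):
        df = EIGHT_ROW.copy()
        df["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_weighted_cox(df, covariate_subset=["z1", "flat"])
        assert "flat" in fit.dropped_covariates
        assert list(fit.coefficients.index) == ["z1"]

    def test_monotone_likelihood_flagged(self):
        # perfectly separated covariate: earlier events all have z=1
        df, names = _frame(np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0]),
                           np.array([1, 1, 1, 1, 1, 1]),
                           np.array([1.0, 1, 1, 0, 0, 0])[:, None])
        fit = fit_weighted_cox(df, covariate_subset=names, max_coef=10.0)
        assert not fit.converged
        assert "diverged" in fit.flags

    def test_json_round_trip(self):
        fit = fit_weighted_cox(EIGHT_ROW, covariate_subset=["z1", "z2"])
        back = LocalCoxFit.from_json(fit.to_json())
        np.testing.assert_allclose(back.coefficients, fit.coefficients)
        np.testing.assert_allclose(back.baseline_cumhaz.values,
                                   fit.baseline_cumhaz.values)
        assert back.converged == fit.converged


class TestPredictRisk:
    def test_null_coefficients_closed_form(self):
        fit = LocalCoxFit(
            coefficients=pd.Series(dtype=float),
            baseline_cumhaz=StepFunction([1.0], [0.3]),
            covariate_center=pd.Series(dtype=float),
            converged=True, n_effective_events=5, loglik=0.0,
            score_norm=0.0, n_iter=0, max_event_time=1.0)
        pred = predict_risk(fit, {}, horizon=1.0)
        assert pred.probability == pytest.approx(1 - np.exp(-0.3), abs=1e-12)

    def test_zero_horizon_probability_zero(self):
        fit = fit_weighted_cox(EIGHT_ROW, covariate_subset=["z1"])
        pred = predict_risk(fit, {"z1": 0.2}, horizon=0.0)
        assert pred.probability == 0.0

    def test_single_event_breslow(self):
        df = pd.DataFrame({"residual_time": [2.0], "event": [1],
                           "z": [0.0]})
        with pytest.warns(UserWarning):  # z constant -> dropped
            fit = fit_weighted_cox(df, covariate_subset=["z"])
        assert fit.baseline_cumhaz(2.0) == pytest.approx(1.0)
        pred = predict_risk(fit, {"z": 0.0}, horizon=2.0)
        assert pred.probability == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_monotone_in_horizon_and_bounded(self):
        fit = fit_weighted_cox(EIGHT_ROW, covariate_subset=["z1", "z2"])
        taus = np.linspace(0, 12, 40)
        probs = [predict_risk(fit, {"z1": 0.4, "z2": 1.0}, h).probability
                 for h in taus]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert (np.diff(probs) >= -1e-15).all()

    def test_extrapolation_flagged(self):
        fit = fit_weighted_cox(EIGHT_ROW, covariate_subset=["z1"])
        pred = predict_risk(fit, {"z1": 0.0}, horizon=100.0)
        assert pred.extrapolated
        near = predict_risk(fit, {"z1": 0.0}, horizon=1.5)
        assert not near.extrapolated
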