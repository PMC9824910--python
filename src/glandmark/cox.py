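"""Weighted Cox proportional hazards on landmark rows (working independence).

The local estimation step of generalized landmark analysis maximizes the
kernel-weighted partial log-likelihood

    l(beta) = sum_ij W_ij d_ij [ eta_ij - log sum_{kl in R(T_ij)} W_kl
                                                     exp(eta_kl) ],

with eta_ij = beta' (Z_ij - center), risk sets R(.) on the residual-time
scale, and Breslow handling of tied residual times.  Repeated rows from one
subject are treated as independent (working independence); uncertainty is
handled downstream by subject-level resampling, so no analytic variance is
computed here.

The weighted Breslow cumulative baseline hazard

    Lambda0(u) = sum_{event times T <= u} [ sum_{tied events} W ]
                                          / sum_{R(T)} W exp(eta)

is returned as a right-continuous step function, and horizon-tau risk is
1 - exp{ -Lambda0(tau) exp(beta' (Z - center)) }.

Weights are normalized internally to mean one over positive-weight rows, so
the fit is exactly invariant to the overall weight scale and convergence
tolerances are scale-free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EVENT_COL, RESIDUAL_COL, LandmarkDataset
from .errors import CoxFitError
from .kernels import WeightVector

__all__ = ["StepFunction", "LocalCoxFit", "RiskPrediction",
           "fit_weighted_cox", "predict_risk", "predict_risk_many"]


class StepFunction:
    """Right-continuous step function, 0 before the first knot."""

    __slots__ = ("knots", "values")

    def __init__(self, knots, values):
        self.knots = np.asarray(knots, dtype=float)
        self.values = np.asarray(values, dtype=float)

    def __call__(self, t):
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float),
                              side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return float(out) if out.ndim == 0 else out

    def left_limit(self, t):
        """Value just before t (left-continuous evaluation)."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float),
                              side="left") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class LocalCoxFit:
    """A fitted (possibly kernel-weighted) Cox model on landmark rows."""

    coefficients: pd.Series
    baseline_cumhaz: StepFunction
    covariate_center: pd.Series
    converged: bool
    n_effective_events: float
    loglik: float
    score_norm: float
    n_iter: int
    max_event_time: float
    dropped_covariates: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def linear_predictor(self, covariates) -> float:
        z = np.array([float(covariates[name])
                      for name in self.coefficients.index])
        c = self.covariate_center.to_numpy(float)
        return float(self.coefficients.to_numpy(float) @ (z - c))

    def to_json(self) -> str:
        return json.dumps({
            "coefficients": self.coefficients.to_dict(),
            "covariate_center": self.covariate_center.to_dict(),
            "baseline_cumhaz": {"knots": self.baseline_cumhaz.knots.tolist(),
                                "values": self.baseline_cumhaz.values.tolist()},
            "converged": self.converged,
            "n_effective_events": self.n_effective_events,
            "loglik": self.loglik,
            "score_norm": self.score_norm,
            "n_iter": self.n_iter,
            "max_event_time": self.max_event_time,
            "dropped_covariates": self.dropped_covariates,
            "flags": self.flags,
        })

    @classmethod
    def from_json(cls, payload: str) -> "LocalCoxFit":
        d = json.loads(payload)
        return cls(
            coefficients=pd.Series(d["coefficients"], dtype=float),
            baseline_cumhaz=StepFunction(d["baseline_cumhaz"]["knots"],
                                         d["baseline_cumhaz"]["values"]),
            covariate_center=pd.Series(d["covariate_center"], dtype=float),
            converged=d["converged"],
            n_effective_events=d["n_effective_events"],
            loglik=d["loglik"], score_norm=d["score_norm"],
            n_iter=d["n_iter"], max_event_time=d["max_event_time"],
            dropped_covariates=d["dropped_covariates"], flags=d["flags"],
        )


@dataclass
class RiskPrediction:
    """Predicted probability of the event within the horizon."""

    probability: float
    horizon: float
    linear_predictor: float
    extrapolated: bool = False


def _prepare(dataset, weights, covariate_subset):
    if isinstance(dataset, LandmarkDataset):
        rows = dataset.rows
        default_covs = dataset.covariate_names
    else:
        rows = dataset
        default_covs = [c for c in rows.columns
                        if c not in (RESIDUAL_COL, EVENT_COL, "subject_id",
                                     "visit_time")]
    covs = list(covariate_subset) if covariate_subset is not None \
        else list(default_covs)

    if weights is None:
        w = np.ones(len(rows))
    elif isinstance(weights, WeightVector):
        w = np.asarray(weights.weights, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != len(rows):
        raise CoxFitError(f"weights length {len(w)} != rows {len(rows)}")
    if (w < 0).any():
        raise CoxFitError("negative weights are not allowed")
    return rows, covs, w


def _partial_loglik(beta, t, d, w, X):
    """Weighted Breslow partial log-likelihood and derivatives.

    Arrays are sorted by ascending residual time; rows sharing a time share
    the risk set of the first row of the tie group.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow far from the optimum
    eta = np.clip(eta, -500, 500)
    r = w * np.exp(eta)

    # reverse cumulative sums: S0[i] = sum_{j >= i} r_j etc.
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    XX = X[:, :, None] * X[:, None, :]
    S2 = np.cumsum((r[:, None, None] * XX)[::-1], axis=0)[::-1]

    # first index of each tie group (rows are sorted by time)
    firsts = np.searchsorted(t, t, side="left")

    ev = d > 0
    we = w[ev]
    fi = firsts[ev]
    s0 = S0[fi]
    ll = float(we @ (eta[ev] - np.log(s0)))
    grad = we @ X[ev] - (we[:, None] * (S1[fi] / s0[:, None])).sum(axis=0)
    zbar = S1[fi] / s0[:, None]
    hess = -(we[:, None, None] * (S2[fi] / s0[:, None, None]
                                  - zbar[:, :, None] * zbar[:, None, :])
             ).sum(axis=0)
    return ll, grad, hess, firsts, S0


def fit_weighted_cox(dataset, weights=None, covariate_subset=None, *,
                     tol_loglik=1e-9, tol_score=1e-7, max_iter=100,
                     max_coef=50.0, max_halvings=20) -> LocalCoxFit:
    """Fit a weighted Cox model with Breslow ties by Newton-Raphson.

    Parameters
    ----------
    dataset : LandmarkDataset or DataFrame
        Must provide ``residual_time``, ``event`` and the covariates.
    weights : array-like, WeightVector or None
        Nonnegative per-row weights; ``None`` means unit weights.
    covariate_subset : list of str, optional
        Covariates entering the linear predictor (default: all).

    Notes
    -----
    Covariates are centered at their weighted means before optimization;
    coefficients are reported on the original scale (centering only shifts
    the baseline hazard, which is recorded together with the center used).
    Covariates constant across positive-weight rows are dropped with a
    warning.  A coefficient norm exceeding ``max_coef`` flags monotone
    likelihood and the fit is returned with ``converged=False``.
    """
    rows, covs, w = _prepare(dataset, weights, covariate_subset)

    keep = w > 0
    sub = rows.loc[keep]
    w = w[keep]
    w = w / w.mean()  # scale invariance + scale-free tolerances

    t = sub[RESIDUAL_COL].to_numpy(float)
    d = sub[EVENT_COL].to_numpy(float)
    n_events_w = float((w * d).sum())
    if not (d > 0).any():
        raise CoxFitError("no events among positive-weight rows")

    X = sub[covs].to_numpy(float) if covs else np.empty((len(sub), 0))
    center = (w[:, None] * X).sum(axis=0) / w.sum() if covs else np.empty(0)
    Xc = X - center

    # drop covariates constant over positive-weight rows
    dropped = []
    if covs:
        spread = np.max(np.abs(Xc), axis=0)
        const = spread <= 1e-12 * (1.0 + np.abs(center))
        if const.any():
            dropped = [c for c, m in zip(covs, const) if m]
            warnings.warn(f"dropping constant covariate(s) {dropped} from "
                          f"the local fit", stacklevel=2)
            keep_cols = ~const
            covs = [c for c, m in zip(covs, const) if not m]
            Xc = Xc[:, keep_cols]
            center = center[keep_cols]

    order = np.argsort(t, kind="mergesort")
    t, d, w, Xc = t[order], d[order], w[order], Xc[order]

    p = Xc.shape[1]
    beta = np.zeros(p)
    flags = []
    ll, grad, hess, firsts, S0 = _partial_loglik(beta, t, d, w, Xc)
    score_norm = float(np.linalg.norm(grad)) if p else 0.0
    it = 0
    for it in range(1, max_iter + 1):
        if p == 0 or score_norm < tol_score:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        new_ll = -np.inf
        for _ in range(max_halvings + 1):
            cand = beta + step
            new_ll, new_grad, new_hess, _, new_S0 = _partial_loglik(
                cand, t, d, w, Xc)
            if new_ll >= ll - 1e-14:
                break
            step = step / 2.0
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll, grad, hess, S0 = cand, new_ll, new_grad, new_hess, new_S0
        score_norm = float(np.linalg.norm(grad))
        if np.linalg.norm(beta) > max_coef:
            flags.append("diverged")
            break
        if rel_change < tol_loglik or score_norm < tol_score:
            break

    converged = (p == 0) or (score_norm < 1e-6 and "diverged" not in flags)
    if not converged and "diverged" not in flags:
        flags.append("max_iter" if it >= max_iter else "stalled")

    # weighted Breslow cumulative baseline hazard at the optimum
    eta = np.clip(Xc @ beta, -500, 500)
    r = w * np.exp(eta)
    S0 = np.cumsum(r[::-1])[::-1]
    firsts = np.searchsorted(t, t, side="left")
    ev = d > 0
    if ev.any():
        ut, inv = np.unique(t[ev], return_inverse=True)
        dsum = np.zeros(len(ut))
        np.add.at(dsum, inv, w[ev])
        # tied events share one risk set; any member's S0 is the group's
        s0u = np.zeros(len(ut))
        s0u[inv] = S0[firsts[np.flatnonzero(ev)]]
        increments = dsum / s0u
        cumhaz = StepFunction(ut, np.cumsum(increments))
        max_event_time = float(ut[-1])
    else:  # unreachable: guarded above
        cumhaz = StepFunction([], [])
        max_event_time = 0.0

    return LocalCoxFit(
        coefficients=pd.Series(beta, index=covs, dtype=float),
        baseline_cumhaz=cumhaz,
        covariate_center=pd.Series(center, index=covs, dtype=float),
        converged=bool(converged),
        n_effective_events=n_events_w,
        loglik=float(ll),
        score_norm=score_norm,
        n_iter=it,
        max_event_time=max_event_time,
        dropped_covariates=dropped,
        flags=flags,
    )


def predict_risk(fit: LocalCoxFit, covariates, horizon: float,
                 allow_unconverged: bool = False) -> RiskPrediction:
    """Horizon-tau event probability 1 - exp{-Lambda0(tau) exp(lp)}.

    ``covariates`` is any mapping providing a value for every coefficient
    name.  A horizon beyond the largest residual event time of the fit yields
    a prediction flagged ``extrapolated`` (the step-function baseline is flat
    there).
    """
    if horizon < 0:
        raise ValueError(f"horizon must be nonnegative, got {horizon}")
    if not fit.converged and not allow_unconverged:
        raise CoxFitError("fit did not converge; pass allow_unconverged=True "
                          "to predict anyway")
    lp = fit.linear_predictor(covariates)
    lam = fit.baseline_cumhaz(horizon)
    prob = 1.0 - np.exp(-lam * np.exp(lp))
    return RiskPrediction(
        probability=float(min(max(prob, 0.0), 1.0)),
        horizon=float(horizon),
        linear_predictor=lp,
        extrapolated=bool(horizon > fit.max_event_time),
    )


def predict_risk_many(fit: LocalCoxFit, queries: pd.DataFrame,
                      horizon: float) -> np.ndarray:
    """Vectorized horizon-tau probabilities for a table of covariate rows."""
    names = list(fit.coefficients.index)
    Z = queries[names].to_numpy(float) if names \
        else np.zeros((len(queries), 0))
    lp = (Z - fit.covariate_center.to_numpy(float)[None, :]) \
        @ fit.coefficients.to_numpy(float) if names else np.zeros(len(queries))
    lam = fit.baseline_cumhaz(horizon)
    return np.clip(1.0 - np.exp(-lam * np.exp(np.clip(lp, -500, 500))),
                   0.0, 1.0)
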