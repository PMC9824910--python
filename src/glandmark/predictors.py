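"""Prediction strategies: static Cox (SPM) and generalized landmark analysis.

Both strategies are scikit-learn-style estimators: construct with
hyper-parameters, ``fit`` on a :class:`~glandmark.cohort.Cohort`, then
``predict_risk(queries, horizon)`` where ``queries`` is a table of covariate
snapshots (one row per prediction visit).

* :class:`StaticCoxRisk` fits a conventional Cox model to the baseline rows
  only (one row per subject) and predicts over ``[0, horizon]`` of the
  baseline time scale; by default the covariates *observed at the prediction
  visit* are plugged in.
* :class:`GLARisk` fits, for every query, a kernel-weighted Cox model
  localized on one or two landmark variables at the query's current value.
  ``landmark_variables=("time",)`` localizes on the visit time and reproduces
  classical landmark analysis; a uniform kernel with span 1 reproduces a
  single pooled Cox "super model" on the stacked landmark dataset.

Localizing on V leaves V's effect inside the (local) baseline hazard; by
default V is additionally adjusted linearly inside each neighborhood
(``adjust_landmark_linear``), except when localizing on time in the classical
landmark-analysis tradition, where the time effect is absorbed entirely into
the baseline hazard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .cohort import (
    EVENT_COL,
    FOLLOWUP_COL,
    RESIDUAL_COL,
    SUBJECT_COL,
    TIME_VARIABLE,
    VISIT_TIME_COL,
    Cohort,
    LandmarkDataset,
    build_landmark_dataset,
)
from .cox import LocalCoxFit, fit_weighted_cox, predict_risk_many
from .errors import CoxFitError, SparseNeighborhoodError
from .evaluation import brier_score, censoring_survival, time_dependent_auc
from .kernels import KernelSpec, compute_weights, landmark_scales

__all__ = ["StaticCoxRisk", "GLARisk", "SpanSelectionResult",
           "fit_spm", "predict_gla", "select_span"]


class StaticCoxRisk(BaseEstimator):
    """Static prediction model: baseline-covariates-only Cox regression.

    Parameters
    ----------
    covariates : list of str or None
        Covariates of the linear predictor (default: every cohort covariate).
    """

    is_static = True

    def __init__(self, covariates=None):
        self.covariates = covariates

    def fit(self, cohort: Cohort, y=None):
        covs = list(self.covariates) if self.covariates is not None \
            else list(cohort.covariate_names)
        base = cohort.baseline_rows()
        frame = base.rename(columns={FOLLOWUP_COL: RESIDUAL_COL})
        self.fit_ = fit_weighted_cox(frame[[RESIDUAL_COL, EVENT_COL, *covs]],
                                     covariate_subset=covs)
        self.covariate_names_ = covs
        self.n_subjects_ = len(base)
        return self

    def predict_risk(self, queries: pd.DataFrame, horizon: float):
        """Event probability within ``horizon`` for each query row."""
        if not hasattr(self, "fit_"):
            raise CoxFitError("estimator is not fitted")
        return predict_risk_many(self.fit_, queries, horizon)


class GLARisk(BaseEstimator):
    """Generalized landmark analysis with kernel-localized Cox fits.

    Parameters
    ----------
    landmark_variables : tuple of str
        One or two covariate names; the reserved name ``"time"`` resolves to
        the visit time (classical landmark analysis).
    kernel : {"epanechnikov", "uniform"}
    span : float in (0, 1] or None
        Adaptive bandwidth: the span-quantile of distances between the query
        and the training landmark values.  Exactly one of ``span`` /
        ``bandwidth`` is set.
    bandwidth : float, tuple or None
        Fixed bandwidth(s) on the (standardized) landmark scale.
    standardize : bool
        Scale each landmark variable by its training SD before distances.
    covariates : list of str or None
        Linear-predictor covariates (default: all cohort covariates except
        the landmark variables).
    adjust_landmark_linear : bool or None
        Also include the landmark variable(s) linearly in the local fit.
        ``None`` (default) resolves to False when localizing on time only,
        True otherwise.
    min_events : float
        Sparse-neighborhood guard passed to the weight computation.
    grid_size : int or None
        When set (univariate localization only), local fits are precomputed
        at ``grid_size`` quantile points of the landmark variable and query
        log cumulative hazards are interpolated linearly between the two
        bracketing grid fits; ``None`` refits at every distinct query value
        (reference semantics).
    warn_missing_time_anchor : bool
        Warn when neither the visit time nor an age-like covariate appears
        anywhere in the model, since the timing of the longitudinal data is
        then lost.
    """

    is_static = False

    def __init__(self, landmark_variables=("time",), kernel="epanechnikov",
                 span=0.5, bandwidth=None, standardize=True, covariates=None,
                 adjust_landmark_linear=None, min_events=10, grid_size=None,
                 warn_missing_time_anchor=True):
        self.landmark_variables = landmark_variables
        self.kernel = kernel
        self.span = span
        self.bandwidth = bandwidth
        self.standardize = standardize
        self.covariates = covariates
        self.adjust_landmark_linear = adjust_landmark_linear
        self.min_events = min_events
        self.grid_size = grid_size
        self.warn_missing_time_anchor = warn_missing_time_anchor

    # -- fitting ------------------------------------------------------------
    def _kernel_spec(self) -> KernelSpec:
        return KernelSpec(landmark_variables=tuple(self.landmark_variables),
                          kernel=self.kernel, span=self.span,
                          bandwidth=self.bandwidth,
                          standardize=self.standardize)

    def fit(self, cohort, y=None):
        if isinstance(cohort, Cohort):
            data = build_landmark_dataset(cohort)
        elif isinstance(cohort, LandmarkDataset):
            data = cohort
        else:
            raise TypeError("fit expects a Cohort or LandmarkDataset")
        spec = self._kernel_spec()
        lvars = tuple(self.landmark_variables)
        lcols = [VISIT_TIME_COL if v == TIME_VARIABLE else v for v in lvars]

        adjust = self.adjust_landmark_linear
        if adjust is None:
            adjust = lvars != (TIME_VARIABLE,)
        if self.covariates is not None:
            covs = list(self.covariates)
        else:
            covs = [c for c in data.covariate_names if c not in lcols]
        linear = list(covs)
        if adjust:
            linear += [c for c in lcols if c not in linear]

        if self.warn_missing_time_anchor:
            anchors = set(lcols) | {c.lower() for c in linear}
            anchored = VISIT_TIME_COL in anchors \
                or any("age" in a for a in anchors)
            if not anchored:
                warnings.warn(
                    "neither the visit time nor an age-like covariate is in "
                    "the model; the timing of the longitudinal data is lost",
                    stacklevel=2)

        self.landmark_data_ = data
        self.kernel_spec_ = spec
        self.landmark_columns_ = lcols
        self.linear_covariates_ = linear
        self.adjust_ = bool(adjust)
        self.scales_ = landmark_scales(data, spec)
        self.n_events_ = data.n_events

        if self.grid_size is not None:
            if len(lvars) != 1:
                raise ValueError("grid precompute supports a single "
                                 "landmark variable")
            v = data.rows[lcols[0]].to_numpy(float)
            qs = np.linspace(0.0, 1.0, int(self.grid_size))
            points, fits = [], []
            for g in np.unique(np.quantile(v, qs)):
                try:
                    fits.append(self._local_fit(np.array([g])))
                    points.append(g)
                except SparseNeighborhoodError:
                    continue  # extreme quantiles may not meet the guard
            if not fits:
                raise SparseNeighborhoodError(
                    "no grid point meets the effective-event guard; "
                    "increase the span or lower min_events")
            if len(points) < len(qs):
                warnings.warn(f"dropped {len(qs) - len(points)} sparse grid "
                              f"point(s) from the precompute", stacklevel=2)
            self.grid_points_ = np.asarray(points)
            self.grid_fits_ = fits
        return self

    def _local_fit(self, vstar: np.ndarray) -> LocalCoxFit:
        wv = compute_weights(self.landmark_data_, self.kernel_spec_, vstar,
                             min_events=self.min_events, scales=self.scales_)
        return fit_weighted_cox(self.landmark_data_, weights=wv,
                                covariate_subset=self.linear_covariates_)

    # -- prediction ---------------------------------------------------------
    def _query_values(self, queries: pd.DataFrame) -> np.ndarray:
        cols = []
        for v, col in zip(self.landmark_variables, self.landmark_columns_):
            if col in queries.columns:
                cols.append(col)
            elif v in queries.columns:  # allow "time" spelled literally
                cols.append(v)
            else:
                raise KeyError(f"queries are missing the landmark variable "
                               f"column {col!r}")
        return queries[cols].to_numpy(float)

    def predict_risk(self, queries: pd.DataFrame, horizon: float,
                     return_details: bool = False):
        """Event probability within ``horizon`` at each query visit.

        Each query row must provide the landmark variable(s) and every
        linear-predictor covariate.
        """
        if not hasattr(self, "landmark_data_"):
            raise CoxFitError("estimator is not fitted")
        V = self._query_values(queries)
        if self.grid_size is not None:
            probs, extrap = self._predict_grid(queries, V, horizon)
        else:
            probs, extrap = self._predict_exact(queries, V, horizon)
        if return_details:
            return pd.DataFrame({"probability": probs,
                                 "extrapolated": extrap})
        return probs

    def _predict_exact(self, queries, V, horizon):
        probs = np.empty(len(queries))
        extrap = np.zeros(len(queries), bool)
        cache: dict[tuple, LocalCoxFit] = {}
        for key, idx in _group_rows(V):
            fit = cache.get(key)
            if fit is None:
                fit = self._local_fit(np.asarray(key, dtype=float))
                cache[key] = fit
            sub = queries.iloc[idx]
            probs[idx] = predict_risk_many(fit, sub, horizon)
            extrap[idx] = horizon > fit.max_event_time
        return probs, extrap

    def _predict_grid(self, queries, V, horizon):
        v = V[:, 0]
        g = self.grid_points_
        # cumulative hazard of every query under every bracketing grid fit
        pos = np.clip(np.searchsorted(g, v), 1, len(g) - 1)
        lo, hi = pos - 1, pos
        frac = np.where(g[hi] > g[lo], (v - g[lo]) / (g[hi] - g[lo]), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        H = np.empty((len(g), len(queries)))
        extrap_g = np.empty(len(g), bool)
        for k, fit in enumerate(self.grid_fits_):
            p = predict_risk_many(fit, queries, horizon)
            H[k] = -np.log(np.clip(1.0 - p, 1e-300, 1.0))
            extrap_g[k] = horizon > fit.max_event_time
        Hq = (1.0 - frac) * H[lo, np.arange(len(queries))] \
            + frac * H[hi, np.arange(len(queries))]
        probs = 1.0 - np.exp(-Hq)
        extrap = extrap_g[lo] | extrap_g[hi]
        return np.clip(probs, 0.0, 1.0), extrap


def _group_rows(V: np.ndarray):
    """Group query rows by (rounded) landmark value; yields (key, indices)."""
    keys = [tuple(np.round(row, 12)) for row in V]
    seen: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        seen.setdefault(k, []).append(i)
    for k, idx in seen.items():
        yield k, np.asarray(idx)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_spm(cohort: Cohort, covariates=None) -> StaticCoxRisk:
    """Fit the static (baseline-only) prediction model."""
    return StaticCoxRisk(covariates=covariates).fit(cohort)


def predict_gla(training, queries, horizon, **gla_params):
    """One-shot GLA prediction: fit on ``training`` (Cohort or
    LandmarkDataset), predict each row of ``queries`` at ``horizon``."""
    return GLARisk(**gla_params).fit(training).predict_risk(queries, horizon)


# ---------------------------------------------------------------------------
# span selection
# ---------------------------------------------------------------------------

@dataclass
class SpanSelectionResult:
    """Cross-validated accuracy per span and the selected value.

    ``selected_span`` is the smallest span whose Brier score lies within one
    bootstrap standard error of the best (smallest) Brier on the grid.
    """

    grid: list[float]
    brier: list[float]
    brier_se: list[float]
    auc: list[float]
    selected_span: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"span": self.grid, "brier": self.brier,
                             "brier_se": self.brier_se, "auc": self.auc,
                             "selected": [s == self.selected_span
                                          for s in self.grid]})


def select_span(cohort: Cohort, estimator: GLARisk, grid, horizon,
                n_splits: int = 2, n_boot: int = 100,
                seed: int = 0) -> SpanSelectionResult:
    """Pick the span by cross-validated Brier score (primary criterion).

    For each span on the grid the cohort's subjects are split in half
    ``n_splits`` times; the estimator is fit on the training half and the
    Brier score and AUC of its predictions at every validation visit are
    averaged over splits.  The bootstrap SE of the Brier score comes from
    ``n_boot`` subject-level resamples of the validation records.  Among
    spans whose Brier is within one SE of the best, the smallest is selected.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("span grid is empty")
    master = np.random.SeedSequence(seed)
    split_seeds = master.spawn(n_splits)
    subjects = cohort.outcomes[SUBJECT_COL].to_numpy()

    per_span = {g: {"brier": [], "auc": [], "var": []} for g in grid}
    feasible = {g: True for g in grid}
    sparse_hint = None

    for sseq in split_seeds:
        rng = np.random.default_rng(sseq)
        perm = rng.permutation(len(subjects))
        half = len(subjects) // 2
        train = cohort.subset(subjects[perm[:half]])
        valid = cohort.subset(subjects[perm[half:]])
        rows = build_landmark_dataset(valid).rows
        t = rows[RESIDUAL_COL].to_numpy(float)
        e = rows[EVENT_COL].to_numpy(float)
        from .evaluation import _resample_rows, _subject_row_indices
        uniq, row_lists = _subject_row_indices(rows[SUBJECT_COL].to_numpy())

        for g in grid:
            if not feasible[g]:
                continue
            est = clone(estimator).set_params(span=g, bandwidth=None)
            try:
                est.fit(train)
                p = np.asarray(est.predict_risk(rows, horizon), float)
            except SparseNeighborhoodError as err:
                feasible[g] = False
                sparse_hint = getattr(err, "suggested_span", None) \
                    or sparse_hint
                continue
            G = censoring_survival(t, e)
            per_span[g]["brier"].append(brier_score(t, e, p, horizon, G))
            per_span[g]["auc"].append(time_dependent_auc(t, e, p, horizon, G))
            boots = []
            for _ in range(n_boot):
                ridx = _resample_rows(rng, uniq, row_lists)
                try:
                    Gb = censoring_survival(t[ridx], e[ridx])
                    boots.append(brier_score(t[ridx], e[ridx], p[ridx],
                                             horizon, Gb))
                except Exception:  # undefined metric on a rare resample
                    continue
            per_span[g]["var"].append(np.var(boots) if boots else np.nan)

    ok = [g for g in grid if feasible[g] and per_span[g]["brier"]]
    if not ok:
        raise SparseNeighborhoodError(
            "every span on the grid failed the sparse-neighborhood guard"
            + (f"; smallest feasible span is about {sparse_hint}"
               if sparse_hint else ""),
            suggested_span=sparse_hint)

    brier = {g: float(np.mean(per_span[g]["brier"])) for g in ok}
    auc = {g: float(np.mean(per_span[g]["auc"])) for g in ok}
    # SE of the split-averaged Brier from per-split bootstrap variances
    se = {g: float(math.sqrt(np.nanmean(per_span[g]["var"])
                             / max(len(per_span[g]["var"]), 1)))
          for g in ok}
    best = min(ok, key=lambda g: brier[g])
    threshold = brier[best] + se[best]
    candidates = [g for g in ok if brier[g] <= threshold]
    selected = min(candidates)

    def _col(d):
        return [d.get(g, float("nan")) for g in grid]

    return SpanSelectionResult(grid=grid, brier=_col(brier), brier_se=_col(se),
                               auc=_col(auc), selected_span=float(selected))
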