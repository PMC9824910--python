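"""Censoring-adjusted dynamic prediction accuracy and its validation protocol.

Discrimination and calibration of horizon-tau risk predictions are measured
by the time-dependent AUC and Brier score under right censoring, using
inverse-probability-of-censoring weights (IPCW):

* cases are records with residual time <= tau and an observed event, weighted
  1/G(T-); controls are records still event-free beyond tau, weighted
  1/G(tau); G is the Kaplan-Meier estimator of the censoring distribution on
  the residual-time scale, pooled over validation rows (working
  independence).
* the AUC is the weighted concordance of predictions over all case-control
  pairs (ties get half credit); with no censoring it reduces exactly to the
  Mann-Whitney statistic.
* the Brier score is the IPCW-weighted mean of (1{T <= tau} - p*)^2; records
  censored before tau get weight zero; with no censoring it is the plain
  mean squared error.

The validation protocol splits subjects in half, fits every method on the
training half, predicts at each eligible validation visit, and reports
per-method AUC/Brier with subject-level bootstrap percentile intervals and
differences against a benchmark (relative for the Brier score, absolute for
the AUC); the split is repeated and results are averaged.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import (
    EVENT_COL,
    RESIDUAL_COL,
    SUBJECT_COL,
    Cohort,
    build_landmark_dataset,
)
from .cox import StepFunction
from .errors import MetricError

__all__ = ["censoring_survival", "time_dependent_auc", "brier_score",
           "cross_validated_compare"]


# ---------------------------------------------------------------------------
# censoring Kaplan-Meier
# ---------------------------------------------------------------------------

def censoring_survival(times, events) -> StepFunction:
    """Kaplan-Meier estimator G(t) of the censoring distribution.

    Censoring (``event == 0``) is treated as the "event" of this estimator
    and observed terminal events censor it.  Implemented directly with numpy
    because it sits inside bootstrap inner loops; it is cross-checked against
    lifelines' product-limit estimator in the test suite.
    """
    t = np.asarray(times, dtype=float)
    c = 1.0 - np.asarray(events, dtype=float)
    if t.size == 0:
        raise MetricError("cannot estimate censoring survival from 0 records")
    order = np.argsort(t, kind="mergesort")
    ts, cs = t[order], c[order]
    ut, first = np.unique(ts, return_index=True)
    at_risk = len(ts) - first
    dc = np.add.reduceat(cs, first)
    jump = dc > 0
    if not jump.any():
        return StepFunction([np.inf], [1.0])
    factors = 1.0 - dc[jump] / at_risk[jump]
    return StepFunction(ut[jump], np.cumprod(factors))


def _km_eval(G: StepFunction, t):
    """G(t) with the convention G = 1 before the first jump."""
    idx = np.searchsorted(G.knots, np.asarray(t, dtype=float), side="right")
    vals = np.concatenate([[1.0], G.values])
    return vals[idx]


def _km_eval_left(G: StepFunction, t):
    """Left limit G(t-)."""
    idx = np.searchsorted(G.knots, np.asarray(t, dtype=float), side="left")
    vals = np.concatenate([[1.0], G.values])
    return vals[idx]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _as_arrays(times, events, predictions):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if not (len(t) == len(e) == len(p)):
        raise MetricError("times/events/predictions length mismatch")
    return t, e, p


def time_dependent_auc(times, events, predictions, horizon,
                       G: StepFunction | None = None) -> float:
    """IPCW time-dependent (cumulative/dynamic) AUC at the horizon.

    Weighted concordance over case-control pairs with half credit for tied
    predictions.  Raises :class:`MetricError` when there is no case, no
    control, or an IPCW weight is undefined (G = 0 where needed).
    """
    t, e, p = _as_arrays(times, events, predictions)
    if G is None:
        G = censoring_survival(t, e)

    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    if not case.any() or not ctrl.any():
        raise MetricError(f"AUC undefined at horizon {horizon}: "
                          f"{int(case.sum())} cases, {int(ctrl.sum())} "
                          f"controls")
    g_case = _km_eval_left(G, t[case])
    g_tau = float(_km_eval(G, horizon))
    if g_tau <= 0 or (g_case <= 0).any():
        raise MetricError(f"censoring survival reaches 0 at or before "
                          f"horizon {horizon}; IPCW weights undefined")
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_tau)

    pc = p[case]
    pk = p[ctrl]
    order = np.argsort(pk, kind="mergesort")
    pk_sorted = pk[order]
    cum_w = np.concatenate([[0.0], np.cumsum(w_ctrl[order])])
    lo = np.searchsorted(pk_sorted, pc, side="left")
    hi = np.searchsorted(pk_sorted, pc, side="right")
    less = cum_w[lo]
    eq = cum_w[hi] - cum_w[lo]
    num = float((w_case * (less + 0.5 * eq)).sum())
    return num / (w_case.sum() * w_ctrl.sum())


def brier_score(times, events, predictions, horizon,
                G: StepFunction | None = None) -> float:
    """IPCW time-dependent Brier score: weighted mean of (1{T<=tau}-p*)^2.

    Record weights: observed events before the horizon get 1/G(T-),
    event-free records beyond the horizon get 1/G(tau), records censored
    before the horizon get 0.  The mean is over all records.
    """
    t, e, p = _as_arrays(times, events, predictions)
    if G is None:
        G = censoring_survival(t, e)

    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    w = np.zeros(len(t))
    if case.any():
        g_case = _km_eval_left(G, t[case])
        if (g_case <= 0).any():
            raise MetricError(f"censoring survival reaches 0 before an "
                              f"event time <= horizon {horizon}")
        w[case] = 1.0 / g_case
    if ctrl.any():
        g_tau = float(_km_eval(G, horizon))
        if g_tau <= 0:
            raise MetricError(f"censoring survival is 0 at horizon "
                              f"{horizon}; IPCW weights undefined")
        w[ctrl] = 1.0 / g_tau
    ind = (t <= horizon).astype(float)
    return float(np.mean(w * (ind - p) ** 2))


# ---------------------------------------------------------------------------
# cross-validated comparison
# ---------------------------------------------------------------------------

def _subject_row_indices(subject_ids: np.ndarray):
    """Map subject -> row positions, as parallel arrays for fast resampling."""
    order = np.argsort(subject_ids, kind="mergesort")
    sorted_ids = subject_ids[order]
    uniq, first = np.unique(sorted_ids, return_index=True)
    bounds = np.append(first, len(sorted_ids))
    return uniq, [order[bounds[k]:bounds[k + 1]] for k in range(len(uniq))]


def _resample_rows(rng, uniq, row_lists):
    picks = rng.integers(0, len(uniq), size=len(uniq))
    return np.concatenate([row_lists[k] for k in picks])


def _metrics_or_nan(t, e, p, horizon, G):
    try:
        return (time_dependent_auc(t, e, p, horizon, G),
                brier_score(t, e, p, horizon, G))
    except MetricError:
        return (np.nan, np.nan)


def cross_validated_compare(cohort: Cohort,
                            methods: Mapping[str, object],
                            benchmark: str,
                            horizons,
                            strata=None,
                            n_splits: int = 5,
                            n_boot: int = 2000,
                            seed: int = 0,
                            bootstrap: str = "refit",
                            spm_covariate_mode: str = "current",
                            return_splits: bool = False):
    """Half-split cross-validated accuracy comparison against a benchmark.

    Parameters
    ----------
    methods : mapping name -> unfitted estimator
        Each estimator must implement ``fit(cohort)`` and
        ``predict_risk(queries, horizon)``; estimators are cloned per split.
    benchmark : str
        Name (key of ``methods``) whose accuracy anchors the differences:
        ``delta_rel_brier = (BS_m - BS_bench)/BS_bench`` and
        ``delta_abs_auc = AUC_m - AUC_bench``.
    strata : list of (label, callable) or None
        Each callable maps the validation landmark rows to a boolean mask
        (e.g., a biomarker band or a visit-time band).  ``None`` evaluates a
        single stratum ``"all"``.
    bootstrap : {"refit", "predictions"}
        ``"refit"`` resamples training subjects (models refit per resample)
        and validation subjects independently; ``"predictions"`` is the
        labeled fast mode that resamples only the validation records,
        holding the fitted models fixed.
    spm_covariate_mode : {"current", "baseline"}
        Whether a static (baseline-trained) model is fed the covariates
        observed at the validation visit (default) or the subject's baseline
        covariates carried forward.

    Returns
    -------
    pandas.DataFrame
        One row per (method, stratum, horizon) with point estimates,
        bootstrap percentile CIs (NaN when ``n_boot == 0``) and benchmark
        differences, averaged over splits.
    """
    if benchmark not in methods:
        raise ValueError(f"benchmark {benchmark!r} is not one of the methods")
    if bootstrap not in ("refit", "predictions"):
        raise ValueError("bootstrap must be 'refit' or 'predictions'")
    strata = strata or [("all", None)]
    horizons = list(np.atleast_1d(horizons))

    records = []
    master = np.random.SeedSequence(seed)
    split_seeds = master.spawn(n_splits)
    subjects = cohort.outcomes[SUBJECT_COL].to_numpy()

    for split, sseq in enumerate(split_seeds):
        rng = np.random.default_rng(sseq)
        perm = rng.permutation(len(subjects))
        half = len(subjects) // 2
        train_ids = subjects[perm[:half]]
        valid_ids = subjects[perm[half:]]
        train_cohort = cohort.subset(train_ids)
        valid_cohort = cohort.subset(valid_ids)

        fitted = {name: clone(est).fit(train_cohort)
                  for name, est in methods.items()}
        valid_rows = build_landmark_dataset(valid_cohort).rows
        queries = _queries_for(valid_rows, valid_cohort, spm_covariate_mode)

        preds = {name: {h: _predict(fitted[name], queries[name], h)
                        for h in horizons}
                 for name in methods}

        sub_ids = valid_rows[SUBJECT_COL].to_numpy()
        uniq, row_lists = _subject_row_indices(sub_ids)
        t_all = valid_rows[RESIDUAL_COL].to_numpy(float)
        e_all = valid_rows[EVENT_COL].to_numpy(float)

        for label, pred_fn in strata:
            mask = np.ones(len(valid_rows), bool) if pred_fn is None \
                else np.asarray(pred_fn(valid_rows), bool)
            if not mask.any():
                warnings.warn(f"stratum {label!r} has no eligible validation "
                              f"visits in split {split}; skipped",
                              stacklevel=2)
                continue
            for h in horizons:
                out = _stratum_metrics(
                    train_cohort, methods, fitted, benchmark, valid_rows,
                    queries,
                    preds, mask, t_all, e_all, uniq, row_lists, h,
                    n_boot, bootstrap, rng, spm_covariate_mode, horizons)
                if out is None:
                    warnings.warn(
                        f"metrics undefined in stratum {label!r} at horizon "
                        f"{h} (split {split}); skipped", stacklevel=2)
                    continue
                for name, row in out.items():
                    records.append({"split": split, "method": name,
                                    "stratum": label, "horizon": h, **row})

    raw = pd.DataFrame.from_records(records)
    if raw.empty:
        raise MetricError("no stratum/horizon produced defined metrics")
    summary = (raw.drop(columns="split")
                  .groupby(["method", "stratum", "horizon"], sort=False)
                  .mean()
                  .reset_index())
    return (summary, raw) if return_splits else summary


def _queries_for(valid_rows, valid_cohort, spm_covariate_mode):
    """Per-method query tables (only the static baseline mode differs)."""
    queries = {"__current__": valid_rows}
    if spm_covariate_mode == "baseline":
        base = valid_cohort.baseline_rows().set_index(SUBJECT_COL)
        carried = valid_rows.copy()
        covs = [c for c in base.columns
                if c not in ("visit_time", "followup_time", "event")]
        for c in covs:
            if c in carried.columns:
                carried[c] = base.loc[carried[SUBJECT_COL], c].to_numpy()
        queries["__baseline__"] = carried

    def pick(est):
        if spm_covariate_mode == "baseline" and getattr(est, "is_static",
                                                        False):
            return queries["__baseline__"]
        return queries["__current__"]

    return _QueryRouter(pick)


class _QueryRouter:
    def __init__(self, pick):
        self._pick = pick

    def __getitem__(self, est_or_name):
        return self._pick


def _predict(est, query_picker, horizon):
    return np.asarray(est.predict_risk(query_picker(est), horizon),
                      dtype=float)


def _stratum_metrics(train_cohort, methods, fitted, benchmark, valid_rows,
                     queries, preds, mask, t_all, e_all, uniq, row_lists,
                     horizon, n_boot, bootstrap, rng, spm_covariate_mode,
                     horizons):
    t, e = t_all[mask], e_all[mask]
    try:
        G = censoring_survival(t, e)
    except MetricError:
        return None

    point = {}
    for name in methods:
        p = preds[name][horizon][mask]
        auc, bs = _metrics_or_nan(t, e, p, horizon, G)
        point[name] = (auc, bs)
    if any(np.isnan(v[0]) or np.isnan(v[1]) for v in point.values()):
        return None

    bench_auc, bench_bs = point[benchmark]
    out = {}
    for name in methods:
        auc, bs = point[name]
        out[name] = {
            "auc": auc, "brier": bs,
            "n_cases": int(((t <= horizon) & (e == 1)).sum()),
            "n_controls": int((t > horizon).sum()),
            "delta_rel_brier": (bs - bench_bs) / bench_bs if bench_bs else
            np.nan,
            "delta_abs_auc": auc - bench_auc,
            "auc_lo": np.nan, "auc_hi": np.nan,
            "brier_lo": np.nan, "brier_hi": np.nan,
            "delta_rel_brier_lo": np.nan, "delta_rel_brier_hi": np.nan,
            "delta_abs_auc_lo": np.nan, "delta_abs_auc_hi": np.nan,
        }
    if n_boot <= 0:
        return out

    # subject-level bootstrap; the mask restricts to the stratum afterwards
    mask_idx = np.flatnonzero(mask)
    in_stratum = np.zeros(len(t_all), bool)
    in_stratum[mask_idx] = True

    boot_stats = {name: {"auc": [], "brier": [], "drb": [], "daa": []}
                  for name in methods}
    for _ in range(n_boot):
        rows = _resample_rows(rng, uniq, row_lists)
        rows = rows[in_stratum[rows]]
        if len(rows) == 0:
            continue
        tb, eb = t_all[rows], e_all[rows]
        try:
            Gb = censoring_survival(tb, eb)
        except MetricError:
            continue
        if bootstrap == "refit":
            refit_preds = _refit_predictions(
                train_cohort, methods, rng, spm_covariate_mode, valid_rows,
                horizon)
            get_p = lambda name: refit_preds[name][rows]  # noqa: E731
        else:
            get_p = lambda name: preds[name][horizon][rows]  # noqa: E731
        vals = {}
        for name in methods:
            vals[name] = _metrics_or_nan(tb, eb, get_p(name), horizon, Gb)
        ba, bb = vals[benchmark]
        for name in methods:
            a, b = vals[name]
            boot_stats[name]["auc"].append(a)
            boot_stats[name]["brier"].append(b)
            boot_stats[name]["drb"].append((b - bb) / bb if bb else np.nan)
            boot_stats[name]["daa"].append(a - ba)

    for name in methods:
        s = boot_stats[name]
        for key, col in (("auc", "auc"), ("brier", "brier"),
                         ("drb", "delta_rel_brier"),
                         ("daa", "delta_abs_auc")):
            arr = np.asarray(s[key], dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size:
                lo, hi = np.percentile(arr, [2.5, 97.5])
                out[name][f"{col}_lo"] = lo
                out[name][f"{col}_hi"] = hi
    return out


def _refit_predictions(train_cohort, methods, rng, spm_covariate_mode,
                       valid_rows, horizon):
    """Refit every method on a training-subject resample, predict the
    original validation rows (training and validation resamples are
    independent).  Predictions use the visit-level (current) covariates."""
    subjects = train_cohort.outcomes[SUBJECT_COL].to_numpy()
    picks = rng.choice(subjects, size=len(subjects), replace=True)
    boot_cohort = _cohort_from_picks(train_cohort, picks)
    out = {}
    for name, est in methods.items():
        model = clone(est).fit(boot_cohort)
        out[name] = np.asarray(model.predict_risk(valid_rows, horizon),
                               dtype=float)
    return out


def _cohort_from_picks(cohort: Cohort, picks) -> Cohort:
    """Cohort of possibly repeated subjects, re-identified uniquely."""
    vis = cohort.visits.set_index(SUBJECT_COL)
    outc = cohort.outcomes.set_index(SUBJECT_COL)
    v_parts, o_parts = [], []
    for k, sid in enumerate(picks):
        new_id = f"{sid}#b{k}"
        vv = vis.loc[[sid]].reset_index(drop=True)
        vv.insert(0, SUBJECT_COL, new_id)
        oo = outc.loc[[sid]].reset_index(drop=True)
        oo.insert(0, SUBJECT_COL, new_id)
        v_parts.append(vv)
        o_parts.append(oo)
    return Cohort(visits=pd.concat(v_parts, ignore_index=True),
                  outcomes=pd.concat(o_parts, ignore_index=True),
                  covariate_names=cohort.covariate_names)
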