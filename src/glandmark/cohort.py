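"""Longitudinal cohort data model and landmark-dataset construction.

A cohort couples a long-format visits table (one row per clinic visit, with
the covariate snapshot observed at that visit) with a one-row-per-subject
outcomes table (observed follow-up time ``T_i`` and event indicator
``delta_i``).  Stacking every visit made while the subject was still at risk,
together with the *residual* time from that visit to the terminal event or
censoring, yields the landmark dataset — the unit of all model fitting in
landmark analysis.

Time is abstract: visit times and follow-up times are numeric offsets from
each subject's baseline, in whatever unit the study uses (the unit must be
consistent across both files).  Calendar dates are not parsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    CohortValidationError,
    EmptyLandmarkError,
    ParseError,
    SchemaError,
)

__all__ = [
    "Cohort",
    "LandmarkDataset",
    "read_cohort",
    "write_cohort",
    "build_landmark_dataset",
    "write_landmark_dataset",
    "add_history_features",
]

#: canonical column names used throughout the package
SUBJECT_COL = "subject_id"
VISIT_TIME_COL = "visit_time"
FOLLOWUP_COL = "followup_time"
EVENT_COL = "event"
RESIDUAL_COL = "residual_time"

#: reserved landmark-variable name resolving to the visit time (classical LA)
TIME_VARIABLE = "time"


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    Parameters
    ----------
    visits : pandas.DataFrame
        Columns ``subject_id``, ``visit_time`` plus one column per covariate.
        Within a subject, visit times are strictly increasing and start at 0.
    outcomes : pandas.DataFrame
        Columns ``subject_id``, ``followup_time``, ``event`` (one row per
        subject; ``event`` is 1 if the terminal event was observed, 0 if
        censored).
    covariate_names : list of str
        Ordered covariate columns of ``visits``.
    """

    visits: pd.DataFrame
    outcomes: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.covariate_names = list(self.covariate_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        v, o = self.visits, self.outcomes
        for col in (SUBJECT_COL, VISIT_TIME_COL, *self.covariate_names):
            if col not in v.columns:
                raise SchemaError(f"visits table is missing column {col!r}")
        for col in (SUBJECT_COL, FOLLOWUP_COL, EVENT_COL):
            if col not in o.columns:
                raise SchemaError(f"outcomes table is missing column {col!r}")

        if o[SUBJECT_COL].duplicated().any():
            dups = o.loc[o[SUBJECT_COL].duplicated(), SUBJECT_COL].tolist()
            raise CohortValidationError(
                f"duplicated subject_id in outcomes: {dups[:5]}")
        if (o[FOLLOWUP_COL] < 0).any():
            raise CohortValidationError("negative followup_time in outcomes")
        if not o[EVENT_COL].isin([0, 1]).all():
            raise CohortValidationError("event must be 0 or 1")

        if (v[VISIT_TIME_COL] < 0).any():
            raise CohortValidationError("negative visit_time in visits")
        dup = v.duplicated(subset=[SUBJECT_COL, VISIT_TIME_COL])
        if dup.any():
            subj = v.loc[dup, SUBJECT_COL].iloc[0]
            raise CohortValidationError(
                f"duplicated (subject_id, visit_time) for subject {subj!r}")

        known = set(o[SUBJECT_COL])
        orphan = ~v[SUBJECT_COL].isin(known)
        if orphan.any():
            subj = v.loc[orphan, SUBJECT_COL].iloc[0]
            raise CohortValidationError(
                f"visit for unknown subject {subj!r} (not in outcomes)")
        missing = known - set(v[SUBJECT_COL])
        if missing:
            raise CohortValidationError(
                f"subjects without any visit: {sorted(missing)[:5]}")

        first = v.sort_values([SUBJECT_COL, VISIT_TIME_COL]) \
                 .groupby(SUBJECT_COL, sort=False)[VISIT_TIME_COL].first()
        bad = first[first != 0]
        if len(bad):
            raise CohortValidationError(
                f"first visit not at time 0 for subjects: "
                f"{bad.index.tolist()[:5]}")

    # -- convenience --------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.outcomes)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def subset(self, subject_ids) -> "Cohort":
        """Restrict the cohort to the given subjects (order preserved)."""
        ids = set(subject_ids)
        return Cohort(
            visits=self.visits[self.visits[SUBJECT_COL].isin(ids)]
                       .reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes[SUBJECT_COL].isin(ids)]
                         .reset_index(drop=True),
            covariate_names=self.covariate_names,
        )

    def baseline_rows(self) -> pd.DataFrame:
        """One row per subject: the time-0 visit merged with the outcome."""
        base = self.visits[self.visits[VISIT_TIME_COL] == 0]
        merged = base.merge(self.outcomes, on=SUBJECT_COL, validate="1:1")
        return merged.reset_index(drop=True)


@dataclass
class LandmarkDataset:
    """Stacked visit-level residual-survival records.

    ``rows`` has columns ``subject_id``, ``visit_time``, ``residual_time``,
    ``event`` plus the covariates; one row per visit made strictly before the
    subject's observed follow-up time.
    """

    rows: pd.DataFrame
    covariate_names: list[str]
    n_dropped_visits: int = 0

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_events(self) -> int:
        return int(self.rows[EVENT_COL].sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "subject_id": SUBJECT_COL,
    "visit_time": VISIT_TIME_COL,
    "followup_time": FOLLOWUP_COL,
    "event": EVENT_COL,
}


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_cohort(visits_path, outcomes_path, schema=None, covariates=None,
                delimiter=None) -> Cohort:
    """Read a cohort from a visits file and an outcomes file.

    Parameters
    ----------
    visits_path, outcomes_path : path-like
        Delimited text files with a header row.  The delimiter is
        auto-detected (comma vs tab) unless ``delimiter`` is given.
    schema : dict, optional
        Maps the canonical names ``subject_id``, ``visit_time``,
        ``followup_time``, ``event`` to the column names used in the files.
    covariates : list of str, optional
        Covariate columns of the visits file.  Defaults to every column that
        is neither the subject id nor the visit time.

    Returns
    -------
    Cohort

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ParseError
        If a covariate cell is non-numeric (the message gives file/row).
    CohortValidationError
        On duplicated (subject, visit_time) pairs or other invariant breaks.
    """
    mapping = dict(_DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)

    vd = delimiter or _sniff_delimiter(visits_path)
    od = delimiter or _sniff_delimiter(outcomes_path)
    visits = pd.read_csv(visits_path, sep=vd, dtype={mapping["subject_id"]: str})
    outcomes = pd.read_csv(outcomes_path, sep=od,
                           dtype={mapping["subject_id"]: str})

    for canon in ("subject_id", "visit_time"):
        if mapping[canon] not in visits.columns:
            raise SchemaError(
                f"visits file {visits_path} is missing column "
                f"{mapping[canon]!r} (for {canon!r})")
    for canon in ("subject_id", "followup_time", "event"):
        if mapping[canon] not in outcomes.columns:
            raise SchemaError(
                f"outcomes file {outcomes_path} is missing column "
                f"{mapping[canon]!r} (for {canon!r})")

    visits = visits.rename(columns={mapping["subject_id"]: SUBJECT_COL,
                                    mapping["visit_time"]: VISIT_TIME_COL})
    outcomes = outcomes.rename(columns={mapping["subject_id"]: SUBJECT_COL,
                                        mapping["followup_time"]: FOLLOWUP_COL,
                                        mapping["event"]: EVENT_COL})

    if covariates is None:
        covariates = [c for c in visits.columns
                      if c not in (SUBJECT_COL, VISIT_TIME_COL)]
    else:
        for c in covariates:
            if c not in visits.columns:
                raise SchemaError(
                    f"visits file {visits_path} is missing covariate {c!r}")

    # numeric coercion with row-level diagnostics (header is line 1)
    for col in [VISIT_TIME_COL, *covariates]:
        coerced = pd.to_numeric(visits[col], errors="coerce")
        bad = coerced.isna() & visits[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {visits[col].iloc[row]!r} in column "
                f"{col!r} of {visits_path}, data row {row + 1}")
        visits[col] = coerced
    for col in (FOLLOWUP_COL, EVENT_COL):
        coerced = pd.to_numeric(outcomes[col], errors="coerce")
        bad = coerced.isna() & outcomes[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {outcomes[col].iloc[row]!r} in column "
                f"{col!r} of {outcomes_path}, data row {row + 1}")
        outcomes[col] = coerced

    # missing covariates are not imputed: drop the offending visits, loudly
    incomplete = visits[covariates].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropped {int(incomplete.sum())} visit row(s) with missing "
            f"covariate values", stacklevel=2)
        visits = visits[~incomplete].reset_index(drop=True)

    visits = visits.sort_values([SUBJECT_COL, VISIT_TIME_COL],
                                kind="mergesort").reset_index(drop=True)
    return Cohort(visits=visits[[SUBJECT_COL, VISIT_TIME_COL, *covariates]],
                  outcomes=outcomes[[SUBJECT_COL, FOLLOWUP_COL, EVENT_COL]],
                  covariate_names=list(covariates))


def write_cohort(cohort: Cohort, visits_path, outcomes_path,
                 delimiter=",") -> None:
    """Write the two cohort tables as delimited text (round-trips with
    :func:`read_cohort` up to column order)."""
    cohort.visits.to_csv(visits_path, sep=delimiter, index=False)
    cohort.outcomes.to_csv(outcomes_path, sep=delimiter, index=False)


def write_landmark_dataset(dataset: LandmarkDataset, path,
                           delimiter=",") -> None:
    """Export the stacked landmark dataset for external survival software."""
    cols = [SUBJECT_COL, VISIT_TIME_COL, RESIDUAL_COL, EVENT_COL,
            *dataset.covariate_names]
    dataset.rows[cols].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# landmark dataset construction
# ---------------------------------------------------------------------------

def build_landmark_dataset(cohort: Cohort) -> LandmarkDataset:
    """Stack per-visit residual-survival records.

    Every visit with ``visit_time < followup_time`` becomes one row with
    ``residual_time = followup_time - visit_time`` and the subject's event
    indicator.  Visits at or after the follow-up time are dropped (strict
    inequality) and counted in ``n_dropped_visits``.

    Raises
    ------
    EmptyLandmarkError
        If no visit is eligible.
    """
    merged = cohort.visits.merge(cohort.outcomes, on=SUBJECT_COL, how="left")
    eligible = merged[VISIT_TIME_COL] < merged[FOLLOWUP_COL]
    n_dropped = int((~eligible).sum())
    rows = merged[eligible].copy()
    if rows.empty:
        raise EmptyLandmarkError("no visit occurs strictly before its "
                                 "subject's followup_time")
    rows[RESIDUAL_COL] = rows[FOLLOWUP_COL] - rows[VISIT_TIME_COL]
    rows[EVENT_COL] = rows[EVENT_COL].astype(int)
    cols = [SUBJECT_COL, VISIT_TIME_COL, RESIDUAL_COL, EVENT_COL,
            *cohort.covariate_names]
    return LandmarkDataset(rows=rows[cols].reset_index(drop=True),
                           covariate_names=list(cohort.covariate_names),
                           n_dropped_visits=n_dropped)


# ---------------------------------------------------------------------------
# longitudinal history features
# ---------------------------------------------------------------------------

def _window_stat(times, values, stat):
    if len(times) < 2:
        return values[-1] if stat == "mean" else 0.0
    if stat == "mean":
        return float(np.mean(values))
    # least-squares slope through the in-window points
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return 0.0
    return float(tc @ y / denom)


def add_history_features(cohort: Cohort, feature_specs) -> Cohort:
    """Append rolling-history summaries of a covariate at each visit.

    Parameters
    ----------
    feature_specs : list of (name, window, statistic)
        ``statistic`` is ``"mean"`` or ``"slope"``.  At each visit the
        statistic is computed over that covariate's values at visits inside
        the window ``[visit_time - window, visit_time]`` (inclusive).  Visits
        with fewer than two in-window observations get slope 0 and mean equal
        to the current value.

    Returns
    -------
    Cohort
        A new cohort whose visits table carries one extra column per spec,
        named ``{name}_{statistic}_{window:g}``.
    """
    visits = cohort.visits.reset_index(drop=True).copy()
    new_names = []
    for name, window, stat in feature_specs:
        if name not in cohort.covariate_names:
            raise SchemaError(f"unknown covariate {name!r} in history spec")
        if window <= 0:
            raise SchemaError(f"window must be positive, got {window}")
        if stat not in ("mean", "slope"):
            raise SchemaError(f"statistic must be 'mean' or 'slope', "
                              f"got {stat!r}")
        col = f"{name}_{stat}_{window:g}"
        out = np.empty(len(visits))
        for _, grp in visits.groupby(SUBJECT_COL, sort=False):
            t = grp[VISIT_TIME_COL].to_numpy(float)
            z = grp[name].to_numpy(float)
            idx = grp.index.to_numpy()
            for k in range(len(t)):
                inwin = (t >= t[k] - window) & (t <= t[k])
                out[idx[k]] = _window_stat(t[inwin], z[inwin], stat)
        visits[col] = out
        new_names.append(col)
    return Cohort(visits=visits, outcomes=cohort.outcomes.copy(),
                  covariate_names=cohort.covariate_names + new_names)
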