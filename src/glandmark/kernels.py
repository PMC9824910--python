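"""Kernel localization weights over landmark rows.

Generalized landmark analysis localizes the fit on one or two *landmark
variables* V: rows of the landmark dataset whose landmark values lie close to
the query subject's current value V* receive larger weights.  With a uniform
kernel this is exactly caliper matching (weight > 0 inside the caliper, 0
outside); with the Epanechnikov kernel weights decay quadratically inside the
bandwidth.  The reserved variable name ``"time"`` resolves to the visit time,
which reproduces classical landmark-analysis localization.

The bandwidth may be fixed, or adaptive via a *span* gamma in (0, 1]: the
bandwidth is then the ceil(gamma*N)-th smallest of the distances between V*
and the N training landmark values, so a uniform kernel is guaranteed at
least ceil(gamma*N) matched rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import TIME_VARIABLE, VISIT_TIME_COL, EVENT_COL, LandmarkDataset
from .errors import (
    DegenerateLocalizationError,
    SchemaError,
    SparseNeighborhoodError,
)

__all__ = ["KernelSpec", "WeightVector", "kernel_value", "span_bandwidth",
           "compute_weights"]

_KERNELS = ("epanechnikov", "uniform")


@dataclass(frozen=True)
class KernelSpec:
    """Localization recipe: landmark variable(s), kernel family, bandwidth.

    Exactly one of ``span`` / ``bandwidth`` is set.  ``bandwidth`` may be a
    scalar or one value per landmark variable; it is interpreted on the
    standardized scale when ``standardize`` is true.
    """

    landmark_variables: tuple[str, ...]
    kernel: str = "epanechnikov"
    span: float | None = 0.5
    bandwidth: float | tuple[float, ...] | None = None
    standardize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "landmark_variables",
                           tuple(self.landmark_variables))
        k = len(self.landmark_variables)
        if not 1 <= k <= 2:
            raise SchemaError("landmark_variables must name 1 or 2 variables")
        if self.kernel not in _KERNELS:
            raise SchemaError(f"kernel must be one of {_KERNELS}, "
                              f"got {self.kernel!r}")
        if (self.span is None) == (self.bandwidth is None):
            raise SchemaError("exactly one of span / bandwidth must be set")
        if self.span is not None and not 0.0 < self.span <= 1.0:
            raise SchemaError(f"span must lie in (0, 1], got {self.span}")
        if self.bandwidth is not None:
            bw = np.atleast_1d(np.asarray(self.bandwidth, dtype=float))
            if (bw <= 0).any():
                raise SchemaError("bandwidth must be positive")
            if len(bw) not in (1, k):
                raise SchemaError("bandwidth must be scalar or one per "
                                  "landmark variable")

    def bandwidths_for(self, n_vars: int) -> np.ndarray | None:
        if self.bandwidth is None:
            return None
        bw = np.atleast_1d(np.asarray(self.bandwidth, dtype=float))
        return np.broadcast_to(bw, (n_vars,)).copy()


@dataclass
class WeightVector:
    """Per-row localization weights W_ij with neighborhood diagnostics."""

    weights: np.ndarray
    query_point: np.ndarray
    bandwidths: np.ndarray
    effective_rows: int
    effective_events: float
    landmark_variables: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.weights)


def kernel_value(kernel: str, scaled_distance, bandwidth: float):
    """Evaluate the kernel at |V* - V| = ``scaled_distance``.

    Epanechnikov: (4h)^-1 (1 - u^2) 1(|u| <= 1) with u = distance / h.
    Uniform:      (2h)^-1 1(|u| <= 1).

    The normalizing constants are immaterial to weighted partial-likelihood
    maximization (weight scale cancels) but are kept for definiteness.
    """
    if bandwidth <= 0:
        raise SchemaError(f"bandwidth must be positive, got {bandwidth}")
    if kernel not in _KERNELS:
        raise SchemaError(f"unknown kernel {kernel!r}")
    d = np.asarray(scaled_distance, dtype=float)
    u = d / bandwidth
    inside = np.abs(u) <= 1.0
    if kernel == "epanechnikov":
        vals = np.where(inside, (1.0 - u * u) / (4.0 * bandwidth), 0.0)
    else:
        vals = np.where(inside, 1.0 / (2.0 * bandwidth), 0.0)
    return vals if vals.ndim else float(vals)


def span_bandwidth(distances, span: float) -> float:
    """Adaptive bandwidth: the ceil(span*N)-th smallest distance.

    If that order statistic is 0 (many rows share the query's landmark
    value), the smallest strictly positive distance is returned instead; if
    every distance is 0 localization is degenerate and an error is raised.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise DegenerateLocalizationError("empty distance collection")
    if not 0.0 < span <= 1.0:
        raise SchemaError(f"span must lie in (0, 1], got {span}")
    k = math.ceil(span * d.size)
    h = float(np.partition(d, k - 1)[k - 1])
    if h > 0:
        return h
    positive = d[d > 0]
    if positive.size == 0:
        raise DegenerateLocalizationError(
            "all distances to the query are zero; the landmark variable is "
            "constant in the training data")
    return float(positive.min())


def _resolve_columns(dataset: LandmarkDataset, names) -> list[str]:
    cols = []
    for name in names:
        col = VISIT_TIME_COL if name == TIME_VARIABLE else name
        if col not in dataset.rows.columns:
            raise SchemaError(f"landmark variable {name!r} not found in the "
                              f"landmark dataset")
        cols.append(col)
    return cols


def compute_weights(dataset: LandmarkDataset, spec: KernelSpec, query_point,
                    min_events: float | None = 10,
                    scales: np.ndarray | None = None) -> WeightVector:
    """Kernel weights of every landmark row relative to a query point.

    Per landmark variable the distance is ``|V*_k - V_ijk|`` (divided by the
    training standard deviation when ``spec.standardize``); the per-variable
    bandwidth comes from :func:`span_bandwidth` or is fixed; a row's weight is
    the product over variables of :func:`kernel_value` (product kernel in the
    bivariate case).

    Parameters
    ----------
    min_events : float or None
        Raise :class:`SparseNeighborhoodError` when the effective event count
        of the neighborhood (kernel-weighted event count, normalized so the
        largest weight counts 1) falls below this.  ``None`` disables the
        guard.
    scales : ndarray, optional
        Pre-computed standardization scales (one per landmark variable);
        intended for callers that fit once and query many times.
    """
    cols = _resolve_columns(dataset, spec.landmark_variables)
    q = np.atleast_1d(np.asarray(query_point, dtype=float))
    if q.size != len(cols):
        raise SchemaError(
            f"query point has dimension {q.size}, expected {len(cols)}")

    values = dataset.rows[cols].to_numpy(float)
    if scales is None:
        scales = landmark_scales(dataset, spec)
    dist = np.abs(values - q[None, :]) / scales[None, :]

    fixed = spec.bandwidths_for(len(cols))
    bandwidths = np.empty(len(cols))
    weights = np.ones(len(values))
    for k in range(len(cols)):
        h = fixed[k] if fixed is not None else span_bandwidth(dist[:, k],
                                                              spec.span)
        bandwidths[k] = h
        weights *= kernel_value(spec.kernel, dist[:, k], h)

    positive = weights > 0
    if not positive.any():
        raise SparseNeighborhoodError(
            "no landmark row has positive weight at the query point; "
            "increase the span or bandwidth")
    wmax = weights.max()
    events = dataset.rows[EVENT_COL].to_numpy(float)
    eff_events = float((weights * events).sum() / wmax)
    eff_rows = int(positive.sum())

    if min_events is not None and eff_events < min_events:
        raise SparseNeighborhoodError(
            f"only {eff_events:.1f} effective events around the query "
            f"(minimum {min_events}); use a larger span",
            effective_events=eff_events, min_events=min_events,
            suggested_span=_suggest_span(dist, dataset, spec, min_events),
        )
    return WeightVector(weights=weights, query_point=q,
                        bandwidths=bandwidths, effective_rows=eff_rows,
                        effective_events=eff_events,
                        landmark_variables=spec.landmark_variables)


def landmark_scales(dataset: LandmarkDataset, spec: KernelSpec) -> np.ndarray:
    """Standardization scales (training SDs, or 1s if disabled)."""
    cols = _resolve_columns(dataset, spec.landmark_variables)
    if not spec.standardize:
        return np.ones(len(cols))
    sd = dataset.rows[cols].to_numpy(float).std(axis=0, ddof=1)
    return np.where(sd > 0, sd, 1.0)


def _suggest_span(dist, dataset, spec, min_events):
    """Smallest grid span meeting the effective-event guard (diagnostic)."""
    events = dataset.rows[EVENT_COL].to_numpy(float)
    for gamma in np.linspace(0.05, 1.0, 20):
        try:
            w = np.ones(dist.shape[0])
            for k in range(dist.shape[1]):
                h = span_bandwidth(dist[:, k], gamma)
                w *= kernel_value(spec.kernel, dist[:, k], h)
            if w.max() > 0 and (w * events).sum() / w.max() >= min_events:
                return float(round(gamma, 2))
        except DegenerateLocalizationError:
            continue
    return None
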