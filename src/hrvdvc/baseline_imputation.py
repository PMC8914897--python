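"""Baseline gap-reconstruction methods: interpolation and deletion.

These are the standard approaches the DVC imputation is compared
against.  For each gap, the number of missing beats is estimated from
the mean of the preceding intervals,

    N = floor(gap duration / mean RR over the last ``lookback`` values),

N placeholder timestamps are spread uniformly over the gap, and their
interval values are produced by a 1-D interpolant (linear,
shape-preserving piecewise cubic, or cubic spline) fitted globally to
interval-versus-timestamp over the valid beats.  No consistency repair
is performed: interpolated ordinates generally do not equal the
timestamp differences, which is precisely the time-dependence loss these
baselines are known for.  ``deletion`` simply leaves gaps unfilled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .dvc_imputation import GapSpec
from .rr_model import PhysioBounds, RRSeries

__all__ = ["ImputationMethod", "detect_discontinuities", "estimate_gap_count",
           "impute_interpolation", "bounds_audit"]

ImputationMethod = Literal["dvc", "linear", "pchip", "spline", "deletion"]

#: Minimum support points per interpolant before falling back to linear.
_MIN_SUPPORT = {"linear": 2, "pchip": 4, "spline": 4}


def detect_discontinuities(series: RRSeries, bounds: PhysioBounds | None = None,
                           tol: float = 1e-6) -> list[GapSpec]:
    """Adjacencies where recorded data is missing, of any span.

    Interpolation pipelines replace every value they deleted, so besides
    long gaps (timestamp difference > ``rr_max``) this also reports
    short holes — adjacencies whose interval does not account for the
    timestamp difference (e.g. after deleting a single artifact beat).
    """
    bounds = bounds or PhysioBounds()
    out = []
    t, rr = series.timestamps, series.intervals
    for i in range(1, len(series)):
        diff = t[i] - t[i - 1]
        if diff > bounds.rr_max or diff - rr[i] > tol:
            out.append(GapSpec(t_start=float(t[i - 1]), t_end=float(t[i]),
                               rr_end=float(rr[i])))
    return out


def estimate_gap_count(gap: GapSpec, series: RRSeries,
                       bounds: PhysioBounds | None = None) -> int:
    """Estimated number of beats lost in a gap.

    ``floor(span / mean RR)`` with the mean taken over up to
    ``lookback`` intervals before the gap (falling back to post-gap
    intervals, then to the global mean, for a gap with no history).
    """
    bounds = bounds or PhysioBounds()
    before = np.flatnonzero(series.timestamps <= gap.t_start + 1e-12)
    if len(before):
        vals = series.intervals[before[-bounds.lookback:]]
    else:
        after = np.flatnonzero(series.timestamps >= gap.t_end - 1e-12)
        vals = series.intervals[after[:bounds.lookback]]
    mean_rr = float(np.mean(vals)) if len(vals) else float(np.mean(series.intervals))
    # snap quotients a float-rounding hair below an integer before flooring
    return max(0, math.floor(gap.span / mean_rr + 1e-9))


def _fit_interpolant(t: np.ndarray, rr: np.ndarray, method: str, log: list[str]):
    if method != "linear" and len(t) < _MIN_SUPPORT[method]:
        log.append(f"{method}: only {len(t)} support points, falling back to linear")
        method = "linear"
    if method == "linear":
        return lambda x: np.interp(x, t, rr)
    if method == "pchip":
        return PchipInterpolator(t, rr)
    if method == "spline":
        return CubicSpline(t, rr, bc_type="not-a-knot")
    raise ValueError(f"unknown interpolation method: {method!r}")


def impute_interpolation(series: RRSeries, method: ImputationMethod,
                         bounds: PhysioBounds | None = None,
                         log: list[str] | None = None) -> RRSeries:
    """Reconstruct gaps with a named interpolation method (or deletion).

    ``deletion`` returns the series unchanged (gaps stay).  Otherwise
    each gap receives its estimated number of beats at equally spaced
    timestamps ``t_start + k * span / (N + 1)``, with values from the
    global interpolant.  Interpolated values may fall outside the
    physiological band (notably for ``spline``); they are deliberately
    kept — use :func:`bounds_audit` to flag them.
    """
    bounds = bounds or PhysioBounds()
    log = log if log is not None else []
    if method == "deletion":
        return series
    if method == "dvc":
        raise ValueError("use hrvdvc.dvc_imputation.impute_dvc for the DVC method")
    gaps = detect_discontinuities(series, bounds)
    if not gaps:
        return series
    if len(series) < 2:
        return series
    interp = _fit_interpolant(series.timestamps, series.intervals, method, log)
    ts_parts = [series.timestamps]
    rr_parts = [series.intervals]
    for gap in gaps:
        n = estimate_gap_count(gap, series, bounds)
        if n == 0:
            continue
        k = np.arange(1, n + 1)
        new_t = gap.t_start + k * gap.span / (n + 1)
        new_rr = np.asarray(interp(new_t), dtype=float)
        # An interpolant crossing zero would produce an invalid interval;
        # keep the ordinate audit-able but the series constructible.
        new_rr = np.maximum(new_rr, 1e-6)
        ts_parts.append(new_t)
        rr_parts.append(new_rr)
    ts = np.concatenate(ts_parts)
    order = np.argsort(ts)
    return RRSeries(timestamps=ts[order],
                    intervals=np.concatenate(rr_parts)[order],
                    label=series.label)


def bounds_audit(series: RRSeries, bounds: PhysioBounds | None = None) -> np.ndarray:
    """Indices of intervals outside the physiological band."""
    bounds = bounds or PhysioBounds()
    rr = series.intervals
    return np.flatnonzero((rr < bounds.rr_min) | (rr > bounds.rr_max))
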