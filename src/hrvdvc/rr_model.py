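"""Core data model for RR-interval (tachogram) time series.

An RR series is the sequence of intervals between successive heartbeats,
each carried by the timestamp of the beat that *ends* the interval.  The
defining structural property of a clean tachogram is that the ordinate
(the interval) equals the difference of successive abscissae (the
timestamps): ``RR_i = T_i - T_{i-1}``.  All downstream repair steps in
this package are designed to preserve that equality, so the model exposes
it as a first-class check (:func:`check_consistency`).

Units are seconds throughout; readers can convert from milliseconds on
ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "RRSeries",
    "PhysioBounds",
    "RRParseError",
    "RRValidationError",
    "check_consistency",
    "read_rr_series",
    "write_rr_series",
]

#: Tolerance for the timestamp/interval equality; float noise only.
CONSISTENCY_TOL = 1e-9


class RRParseError(ValueError):
    """Raised when an on-disk RR file cannot be parsed."""


class RRValidationError(ValueError):
    """Raised when arrays do not form a valid RR series."""


@dataclass(frozen=True)
class PhysioBounds:
    """Physiological plausibility bounds for RR intervals.

    Parameters
    ----------
    rr_min, rr_max
        Hard limits on a plausible inter-beat interval, in seconds.  The
        defaults (0.3 s and 1.3 s, i.e. 200 and ~46 bpm) bracket the
        range attainable outside pathological rhythms; intervals beyond
        them are treated as detection artifacts.
    max_deviation
        Ceiling on the mean absolute successive relative difference used
        as the local variability budget when accepting a repaired beat
        (dimensionless fraction, default 0.4 = twice the largest normal
        beat-to-beat swing).
    lookback
        Number of preceding interval pairs used for local statistics
        (variability budget, gap Gaussian fit, gap-size estimate).
    """

    rr_min: float = 0.3
    rr_max: float = 1.3
    max_deviation: float = 0.4
    lookback: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.rr_min < self.rr_max):
            raise RRValidationError(
                f"require 0 < rr_min < rr_max, got {self.rr_min}, {self.rr_max}"
            )
        if not (0 < self.max_deviation <= 1):
            raise RRValidationError(f"max_deviation must be in (0, 1]: {self.max_deviation}")
        if self.lookback < 1:
            raise RRValidationError(f"lookback must be >= 1: {self.lookback}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhysioBounds":
        """Load bounds from a JSON config mapping field names to values."""
        with open(path) as fh:
            payload = json.load(fh)
        allowed = {"rr_min", "rr_max", "max_deviation", "lookback"}
        unknown = set(payload) - allowed
        if unknown:
            raise RRValidationError(f"unknown PhysioBounds fields: {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class RRSeries:
    """An ordered RR-interval time series.

    ``timestamps[i]`` is the time (seconds since recording start) of the
    beat ending interval ``intervals[i]``; timestamps are strictly
    increasing and every interval is positive.  ``label`` is an optional
    free-text condition tag (e.g. ``"stress"`` or ``"relax"``).
    """

    timestamps: np.ndarray
    intervals: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        rr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "intervals", rr)
        if t.ndim != 1 or rr.ndim != 1:
            raise RRValidationError("timestamps and intervals must be 1-D")
        if len(t) != len(rr):
            raise RRValidationError(
                f"length mismatch: {len(t)} timestamps vs {len(rr)} intervals"
            )
        if len(t) and np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise RRValidationError(f"timestamps not strictly increasing at index {bad}")
        if len(rr) and np.any(rr <= 0):
            bad = int(np.flatnonzero(rr <= 0)[0])
            raise RRValidationError(f"non-positive interval at index {bad}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Total covered time, including the span of the first interval."""
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.start_time)

    @property
    def start_time(self) -> float:
        """Time origin: start of the first interval."""
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[0] - self.intervals[0])

    @classmethod
    def from_intervals(cls, intervals: Iterable[float], label: str | None = None,
                       t0: float = 0.0) -> "RRSeries":
        """Build a fully consistent series from intervals alone.

        Timestamps are the cumulative sum offset by ``t0`` (so the first
        beat lands at ``t0 + intervals[0]``).
        """
        rr = np.asarray(list(intervals), dtype=float)
        return cls(timestamps=t0 + np.cumsum(rr), intervals=rr, label=label)

    def with_label(self, label: str | None) -> "RRSeries":
        return replace(self, label=label)


def check_consistency(series: RRSeries, tol: float = CONSISTENCY_TOL,
                      bounds: PhysioBounds | None = None) -> list[int]:
    """Indices where the interval disagrees with the timestamp difference.

    An adjacency whose timestamp difference exceeds ``bounds.rr_max`` is a
    *gap* (lost beats) rather than an inconsistency and is not reported
    here; gaps are enumerated by :func:`hrvdvc.dvc_imputation.detect_gaps`.
    An empty return means the series is fully consistent.
    """
    if bounds is None:
        bounds = PhysioBounds()
    if len(series) < 2:
        return []
    diffs = np.diff(series.timestamps)
    mismatch = np.abs(series.intervals[1:] - diffs) > tol
    not_gap = diffs <= bounds.rr_max
    return [int(i) + 1 for i in np.flatnonzero(mismatch & not_gap)]


def _parse_lines(path: Path, units_scale: float, dialect: str) -> RRSeries:
    ts: list[float] = []
    rr: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise RRParseError(f"{path}:{lineno}: cannot parse {line!r}") from exc
            if dialect == "two-column":
                if len(values) != 2:
                    raise RRParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(values)}"
                    )
                ts.append(values[0] * units_scale)
                rr.append(values[1] * units_scale)
            else:
                if len(values) != 1:
                    raise RRParseError(
                        f"{path}:{lineno}: expected 1 column, got {len(values)}"
                    )
                rr.append(values[0] * units_scale)
    if dialect == "two-column":
        return RRSeries(timestamps=np.asarray(ts), intervals=np.asarray(rr))
    return RRSeries.from_intervals(rr)


def read_rr_series(path: str | Path,
                   dialect: Literal["two-column", "intervals-only"] = "two-column",
                   units: Literal["s", "ms"] = "s") -> RRSeries:
    """Read an RR series from a plain-text/CSV file.

    Two dialects are supported: ``two-column`` files carry
    ``timestamp,interval`` per line; ``intervals-only`` files carry one
    interval per line, timestamps being reconstructed by cumulative sum
    (first beat at ``T0 = RR0``), which is fully consistent by
    construction.  Comma or whitespace separated; lines starting with
    ``#`` are comments.  ``units="ms"`` divides by 1000 on ingest.
    """
    path = Path(path)
    if dialect not in ("two-column", "intervals-only"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    scale = 1e-3 if units == "ms" else 1.0
    return _parse_lines(path, scale, dialect)


def write_rr_series(series: RRSeries, path: str | Path,
                    dialect: Literal["two-column", "intervals-only"] = "two-column") -> None:
    """Write a series back to disk in one of the two text dialects.

    Values are printed with enough digits to round-trip float64 exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "two-column":
            fh.write("# timestamp_s,rr_s\n")
            for t, r in zip(series.timestamps, series.intervals):
                fh.write(f"{float(t)!r},{float(r)!r}\n")
        elif dialect == "intervals-only":
            fh.write("# rr_s\n")
            for r in series.intervals:
                fh.write(f"{float(r)!r}\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")
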