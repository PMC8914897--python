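"""Time-, frequency- and non-linear-domain HRV features.

Features are computed over sliding windows (default 5 min with a 1 min
slide, which avoids edge discontinuities and suits quasi-real-time
analysis):

* time domain — SDNN (sample standard deviation of intervals), RMSSD
  (root mean square of successive differences), NN50/pNN50 (count and
  percentage of successive differences exceeding 50 ms);
* frequency domain — LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) band powers
  of the tachogram resampled at 8 Hz, via an FFT-based Welch
  periodogram, and their ratio.  ULF/VLF need recordings far longer
  than a sliding window and are not computed;
* non-linear — Poincaré-plot SD1/SD2 through the standard
  ellipse-rotation identities
  ``SD1^2 = Var(RR_{i+1} - RR_i) / 2`` and
  ``SD2^2 = 2 Var(RR) - Var(RR_{i+1} - RR_i) / 2``.

All outputs are in milliseconds (powers in ms^2); undefined features are
reported as NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .rr_model import RRSeries

__all__ = [
    "FeatureWindow",
    "sdnn",
    "rmssd",
    "pnn50",
    "poincare_sd",
    "spectral_powers",
    "sliding_windows",
    "features_table",
    "engineer_features",
    "BASE_FEATURES",
]

RESAMPLE_HZ = 8.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
#: Minimum window durations for a defined estimate (seconds).
LF_MIN_DURATION = 120.0
HF_MIN_DURATION = 60.0

#: Feature columns used for pairwise feature engineering, in the order
#: that fixes ratio direction (numerator first): RMSSD/SDNN, not the
#: reverse.
BASE_FEATURES = ["rmssd", "sdnn", "nn50", "pnn50", "lf_power", "hf_power",
                 "lf_hf_ratio", "sd1", "sd2"]


@dataclass(frozen=True)
class FeatureWindow:
    """One analysis window's HRV feature vector (ms-scaled)."""

    t0: float
    sdnn: float
    rmssd: float
    nn50: float
    pnn50: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    sd1: float
    sd2: float
    n_beats: int


def sdnn(intervals: np.ndarray) -> float:
    """Sample standard deviation of the intervals, in ms (NaN for N < 2)."""
    rr = np.asarray(intervals, dtype=float)
    if len(rr) < 2:
        return float("nan")
    return float(np.std(rr, ddof=1) * 1e3)


def rmssd(intervals: np.ndarray) -> float:
    """Root mean square of successive differences, in ms (NaN for N < 2)."""
    rr = np.asarray(intervals, dtype=float)
    if len(rr) < 2:
        return float("nan")
    d = np.diff(rr)
    return float(np.sqrt(np.sum(d**2) / (len(rr) - 1)) * 1e3)


def pnn50(intervals: np.ndarray, threshold_ms: float = 50.0) -> tuple[float, float]:
    """(NN50, pNN50): successive pairs differing by more than 50 ms."""
    rr = np.asarray(intervals, dtype=float)
    if len(rr) < 2:
        return float("nan"), float("nan")
    d = np.abs(np.diff(rr)) * 1e3
    nn = int(np.sum(d > threshold_ms))
    return float(nn), 100.0 * nn / (len(rr) - 1)


def poincare_sd(intervals: np.ndarray) -> tuple[float, float]:
    """Poincaré-plot SD1/SD2 in ms (NaN for N < 3).

    Negative radicands from float noise are clamped to zero.
    """
    rr = np.asarray(intervals, dtype=float)
    if len(rr) < 3:
        return float("nan"), float("nan")
    var_d = np.var(np.diff(rr), ddof=1)
    var_rr = np.var(rr, ddof=1)
    sd1 = np.sqrt(max(var_d / 2.0, 0.0))
    sd2 = np.sqrt(max(2.0 * var_rr - var_d / 2.0, 0.0))
    return float(sd1 * 1e3), float(sd2 * 1e3)


def spectral_powers(series: RRSeries,
                    resample_hz: float = RESAMPLE_HZ) -> tuple[float, float, float]:
    """LF/HF band powers (ms^2) and their ratio for one window.

    The tachogram is interpolated (cubic) onto a uniform grid at
    ``resample_hz``, mean-detrended and fed to a Welch periodogram with
    segments of up to two minutes; band powers are the PSD integrated
    over 0.04–0.15 Hz (LF) and 0.15–0.4 Hz (HF).  LF requires at least
    two minutes of data, HF one minute; shorter windows give NaN.  The
    ratio is NaN when HF is zero.
    """
    n = len(series)
    if n < 4:
        return float("nan"), float("nan"), float("nan")
    t = series.timestamps
    duration = float(t[-1] - t[0])
    if duration < HF_MIN_DURATION:
        return float("nan"), float("nan"), float("nan")
    rr_ms = series.intervals * 1e3
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = CubicSpline(t, rr_ms)(grid)
    x = x - np.mean(x)
    nperseg = min(len(x), int(120 * resample_hz))
    freqs, psd = welch(x, fs=resample_hz, nperseg=nperseg)
    def band_power(lo: float, hi: float, closed_hi: bool) -> float:
        mask = (freqs >= lo) & ((freqs <= hi) if closed_hi else (freqs < hi))
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))
    hf = band_power(*HF_BAND, closed_hi=True)
    lf = band_power(*LF_BAND, closed_hi=False) if duration >= LF_MIN_DURATION \
        else float("nan")
    ratio = lf / hf if hf > 0 else float("nan")
    return lf, hf, ratio


def _window_features(sub: RRSeries, t0: float) -> FeatureWindow:
    rr = sub.intervals
    nn, p50 = pnn50(rr)
    sd1, sd2 = poincare_sd(rr)
    lf, hf, ratio = spectral_powers(sub)
    return FeatureWindow(t0=t0, sdnn=sdnn(rr), rmssd=rmssd(rr), nn50=nn,
                         pnn50=p50, lf_power=lf, hf_power=hf,
                         lf_hf_ratio=ratio, sd1=sd1, sd2=sd2,
                         n_beats=len(rr))


def sliding_windows(series: RRSeries, window_s: float = 300.0,
                    step_s: float = 60.0) -> list[FeatureWindow]:
    """Feature vectors over sliding windows ``[t0, t0 + window_s)``.

    ``t0`` is measured from the recording origin (start of the first
    interval) in steps of ``step_s``; a trailing stretch shorter than a
    full window is dropped.
    """
    duration = series.duration
    if duration < window_s:
        return []
    origin = series.start_time
    # epsilon-snap so a duration a rounding hair under a full window count
    # still yields that window
    n_windows = int(np.floor((duration - window_s) / step_s + 1e-9)) + 1
    out = []
    for k in range(n_windows):
        t0 = k * step_s
        lo, hi = origin + t0, origin + t0 + window_s
        mask = (series.timestamps >= lo) & (series.timestamps < hi)
        sub = RRSeries(series.timestamps[mask], series.intervals[mask],
                       label=series.label)
        out.append(_window_features(sub, t0))
    return out


def features_table(series: RRSeries, window_s: float = 300.0,
                   step_s: float = 60.0) -> pd.DataFrame:
    """Sliding-window features as a DataFrame (one row per window)."""
    wins = sliding_windows(series, window_s, step_s)
    cols = [f.name for f in dc_fields(FeatureWindow)]
    return pd.DataFrame([{c: getattr(w, c) for c in cols} for w in wins],
                        columns=cols)


def engineer_features(base: pd.DataFrame,
                      columns: list[str] | None = None) -> pd.DataFrame:
    """Expand features with every pairwise product and ratio.

    For each unordered pair (f, g) of base columns — f preceding g in
    ``columns`` order — two derived columns are added: ``f_x_g`` and
    ``f_div_g``.  Zero denominators yield NaN, never infinities.  Not
    every derived feature has a physiological reading; a downstream
    classifier is expected to select the informative ones.
    """
    columns = columns or [c for c in BASE_FEATURES if c in base.columns]
    out = base.copy()
    for f, g in itertools.combinations(columns, 2):
        out[f"{f}_x_{g}"] = base[f] * base[g]
        denom = base[g].replace(0.0, np.nan)
        out[f"{f}_div_{g}"] = base[f] / denom
    return out
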