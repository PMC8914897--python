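"""Synthetic RR-series generation and controlled degradation.

The generator lays beats down sequentially from an instantaneous
interval function — mean level plus LF (~0.1 Hz, sympathetic-dominated)
and HF (~0.25 Hz, respiratory) sinusoidal modulation plus white Gaussian
jitter scaled to hit a target SDNN — so the output is fully consistent
by construction, in the spirit of integral-pulse-frequency-modulation
models.  Two presets emulate the study conditions of a stress-detection
protocol: ``relax`` (longer mean interval, stronger respiratory
modulation) and ``stress`` (shorter mean interval, stronger LF
modulation).

Degradation emulates ambulatory signal loss with ground truth retained:
a random fraction of beats is deleted (creating gaps), and a disjoint
random fraction of beats receives a spurious extra peak that splits the
interval into a sub-``rr_min`` ectopic part and a remainder — the
artifact mechanism the ectopic filter is designed to undo.  An
alternative ``replace`` mode substitutes the interval value directly and
shifts the beat's timestamp to keep the equality local to the injected
beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rr_model import PhysioBounds, RRSeries, RRValidationError

__all__ = ["DegradationPlan", "simulate_rr", "simulate_preset", "degrade",
           "restore_deleted", "stress_relax_corpus", "PRESETS"]

#: Condition presets: acute stress shortens the mean interval, suppresses
#: overall variability (SDNN) and respiratory (HF) modulation, and shifts
#: autonomic balance toward LF; relaxation shows the opposite pattern.
#: Mean intervals are chosen so that twice the mean clearly exceeds
#: ``rr_max``: a single missed beat then always surfaces as a deletable
#: long interval, the regime the fixed physiological bounds assume.
PRESETS: dict[str, dict] = {
    "relax": dict(mean_rr=0.92, sdnn_target=0.065, lf_amp=0.025, hf_amp=0.05,
                  lf_hz=0.1, hf_hz=0.25),
    "stress": dict(mean_rr=0.78, sdnn_target=0.035, lf_amp=0.035, hf_amp=0.01,
                   lf_hz=0.1, hf_hz=0.25),
}


@dataclass(frozen=True)
class DegradationPlan:
    """Ground truth of one degradation run (original-series indexing)."""

    deleted_fraction: float
    ectopic_fraction: float
    deleted_indices: np.ndarray
    ectopic_indices: np.ndarray
    seed: int
    mode: str = "split"
    deleted_timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    deleted_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))
    ectopic_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    seam_timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    seam_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate_rr(duration_s: float, mean_rr: float = 0.8,
                sdnn_target: float = 0.05, lf_amp: float = 0.03,
                hf_amp: float = 0.03, lf_hz: float = 0.1, hf_hz: float = 0.25,
                seed: int = 0, label: str | None = None,
                drift_amp: float = 0.0, drift_hz: float = 0.003,
                bounds: PhysioBounds | None = None) -> RRSeries:
    """Simulate a fully consistent RR series.

    The instantaneous interval at beat time t is

        RR(t) = mean_rr + lf_amp sin(2 pi lf_hz t) + hf_amp sin(2 pi hf_hz t)
                + drift_amp sin(2 pi drift_hz t) + jitter,

    with white Gaussian jitter whose variance tops up the sinusoidal
    variance to ``sdnn_target**2``.  Any beat falling outside the
    physiological band raises a validation error (choose amplitudes with
    headroom).
    """
    bounds = bounds or PhysioBounds()
    var_sin = (lf_amp**2 + hf_amp**2 + drift_amp**2) / 2.0
    jitter_sd = float(np.sqrt(max(sdnn_target**2 - var_sin, 0.0)))
    rng = np.random.default_rng(seed)
    t = 0.0
    ts: list[float] = []
    rr: list[float] = []
    while t < duration_s:
        v = (mean_rr
             + lf_amp * np.sin(2 * np.pi * lf_hz * t)
             + hf_amp * np.sin(2 * np.pi * hf_hz * t)
             + drift_amp * np.sin(2 * np.pi * drift_hz * t)
             + jitter_sd * rng.standard_normal())
        if not (bounds.rr_min < v < bounds.rr_max):
            raise RRValidationError(
                f"simulated interval {v:.3f}s at t={t:.1f}s leaves "
                f"[{bounds.rr_min}, {bounds.rr_max}]; reduce amplitudes/jitter"
            )
        t += v
        ts.append(t)
        rr.append(v)
    return RRSeries(np.asarray(ts), np.asarray(rr), label=label)


def simulate_preset(preset: str, duration_s: float, seed: int = 0,
                    **overrides) -> RRSeries:
    """Simulate one of the named condition presets ("relax"/"stress")."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = {**PRESETS[preset], **overrides}
    return simulate_rr(duration_s, seed=seed, label=preset, **params)


def _pick_burst_indices(rng: np.random.Generator, n: int, k: int,
                        mean_run: float = 4.0) -> np.ndarray:
    chosen: set[int] = set()
    while len(chosen) < k:
        start = int(rng.integers(0, n))
        run = 1 + int(rng.geometric(1.0 / mean_run))
        for i in range(start, min(start + run, n)):
            if len(chosen) >= k:
                break
            chosen.add(i)
    return np.asarray(sorted(chosen))


def degrade(series: RRSeries, missing_pct: float, ectopic_pct: float,
            seed: int = 0, burst: bool = False, ectopic_mode: str = "split",
            bounds: PhysioBounds | None = None) -> tuple[RRSeries, DegradationPlan]:
    """Randomly delete beats and inject sub-``rr_min`` ectopic intervals.

    ``round(n * missing_pct / 100)`` beats are removed (beat-wise uniform
    by default; ``burst=True`` deletes contiguous runs, emulating
    ambulatory dropouts) and a disjoint ``round(n * ectopic_pct / 100)``
    beats are corrupted.  Deletion emulates missed peak detections: the
    surviving beat after a deleted run carries the peak-to-peak time
    difference as its interval, exactly as a detector re-deriving
    intervals from the remaining peaks would report it (runs spanning
    more than ``rr_max`` thus surface as long out-of-bounds intervals
    for the filter to delete, which is how gaps arise downstream).

    In the default ``split`` ectopic mode a spurious extra peak splits a
    corrupted beat's interval R into an ectopic part
    u ~ U[0.1, min(rr_min, R - rr_min)) and the remainder R - u — the
    artifact mechanism behind most sub-``rr_min`` intervals in practice
    (an additional detection between two true beats).  The series stays
    fully consistent, so every downstream consistency violation is
    attributable to the pipeline rather than to the corruption itself.
    ``replace`` mode instead overwrites the interval value with
    u ~ U[0.1, rr_min), timestamps untouched: the information the true
    value carried is destroyed, as when a detector mis-places a peak.
    Percentages are of beat count.
    """
    bounds = bounds or PhysioBounds()
    if not (0 <= missing_pct < 50 and 0 <= ectopic_pct < 50):
        raise ValueError("percentages must be in [0, 50)")
    n = len(series)
    n_del = round(n * missing_pct / 100.0)
    n_ect = round(n * ectopic_pct / 100.0)
    if n_del + n_ect > n:
        raise ValueError("requested degradation exceeds available beats")
    rng = np.random.default_rng(seed)
    if burst:
        deleted = _pick_burst_indices(rng, n, n_del) if n_del else np.empty(0, int)
    else:
        deleted = np.sort(rng.choice(n, size=n_del, replace=False)) if n_del \
            else np.empty(0, int)
    del_set = set(int(i) for i in deleted)

    # Split-mode candidates must leave an in-bounds remainder and must
    # not sit right after a deleted beat (the recomputed seam interval
    # would swallow the injected sub-rr_min value).
    min_u = 0.1
    eligible = np.asarray([i for i in range(n)
                           if i not in del_set and (i - 1) not in del_set
                           and (ectopic_mode == "replace"
                                or series.intervals[i] - bounds.rr_min > min_u)])
    if n_ect > len(eligible):
        raise ValueError("not enough eligible beats for ectopic injection")
    ectopic = np.sort(rng.choice(eligible, size=n_ect, replace=False)) if n_ect \
        else np.empty(0, int)
    ect_set = {int(i) for i in ectopic}
    u_values = {}
    for i in ect_set:
        if ectopic_mode == "replace":
            hi = bounds.rr_min
        else:
            hi = min(bounds.rr_min, float(series.intervals[i]) - bounds.rr_min)
        u_values[i] = float(rng.uniform(min_u, hi))

    ts_out: list[float] = []
    rr_out: list[float] = []
    seam_idx: list[int] = []
    seam_rr: list[float] = []
    prev_t = series.start_time
    for i in range(n):
        t_i, r_i = float(series.timestamps[i]), float(series.intervals[i])
        if i in del_set:
            continue
        if (i - 1) in del_set:  # seam: interval re-derived from peak times
            seam_idx.append(i)
            seam_rr.append(r_i)
            r_i = t_i - prev_t
        if i in ect_set and ectopic_mode == "split":
            u = u_values[i]
            ts_out.extend([t_i - r_i + u, t_i])
            rr_out.extend([u, r_i - u])
        elif i in ect_set:  # replace: overwrite the ordinate in place
            ts_out.append(t_i)
            rr_out.append(u_values[i])
        else:
            ts_out.append(t_i)
            rr_out.append(r_i)
        prev_t = t_i

    plan = DegradationPlan(
        deleted_fraction=missing_pct / 100.0,
        ectopic_fraction=ectopic_pct / 100.0,
        deleted_indices=deleted.astype(int),
        ectopic_indices=ectopic.astype(int),
        seed=seed,
        mode=ectopic_mode,
        deleted_timestamps=series.timestamps[deleted.astype(int)],
        deleted_intervals=series.intervals[deleted.astype(int)],
        ectopic_values=np.asarray([u_values[int(i)] for i in ectopic]),
        seam_timestamps=np.asarray([series.timestamps[i] for i in seam_idx]),
        seam_intervals=np.asarray(seam_rr),
    )
    return RRSeries(np.asarray(ts_out), np.asarray(rr_out),
                    label=series.label), plan


def restore_deleted(degraded: RRSeries, plan: DegradationPlan) -> RRSeries:
    """Re-insert the deleted beats recorded in the plan (exact inverse
    of the deletion part of :func:`degrade`), restoring the seam
    intervals that deletion had merged."""
    ts = np.concatenate([degraded.timestamps, plan.deleted_timestamps])
    rr = np.concatenate([degraded.intervals, plan.deleted_intervals])
    order = np.argsort(ts)
    ts, rr = ts[order], rr[order]
    for t_seam, r_seam in zip(plan.seam_timestamps, plan.seam_intervals):
        j = int(np.searchsorted(ts, t_seam))
        rr[j] = r_seam
    return RRSeries(ts, rr, label=degraded.label)


def stress_relax_corpus(n_per_class: int = 12, duration_s: float = 600.0,
                        seed: int = 0, raw_missing_pct: float = 1.0,
                        raw_ectopic_pct: float = 2.0) -> list[RRSeries]:
    """A labelled two-condition corpus with per-subject variation.

    Each series draws its own mean interval and modulation amplitudes
    around the preset values (subject heterogeneity), so the two
    conditions overlap enough for classification to be non-trivial.
    Emulating raw ambulatory recordings, each series also carries a
    small intrinsic artifact load (up to ``raw_missing_pct`` of beats
    missing and ``raw_ectopic_pct`` replaced by ectopic values, drawn
    uniformly per subject): a classifier trained on such originals has
    seen artifact-inflated feature windows, as real training data always
    contain some.
    """
    rng = np.random.default_rng(seed)
    corpus: list[RRSeries] = []
    for label in ("relax", "stress"):
        base = PRESETS[label]
        for k in range(n_per_class):
            params = dict(
                mean_rr=base["mean_rr"] + rng.uniform(-0.05, 0.05),
                sdnn_target=base["sdnn_target"] * rng.uniform(0.8, 1.2),
                lf_amp=base["lf_amp"] * rng.uniform(0.7, 1.3),
                hf_amp=base["hf_amp"] * rng.uniform(0.7, 1.3),
                lf_hz=base["lf_hz"], hf_hz=base["hf_hz"],
            )
            clean = simulate_rr(duration_s, seed=int(rng.integers(2**31)),
                                label=label, **params)
            raw, _ = degrade(clean,
                             missing_pct=rng.uniform(0, raw_missing_pct),
                             ectopic_pct=rng.uniform(0, raw_ectopic_pct),
                             seed=int(rng.integers(2**31)))
            corpus.append(raw)
    return corpus
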