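"""Physiologically validated ectopic-beat filtering for RR series.

Intervals longer than ``rr_max`` are deleted outright (leaving a gap for
the imputation stage), while intervals shorter than ``rr_min`` — which in
ambulatory recordings are almost always a spurious extra peak detected
between two true beats — are *merged* into a neighbour so that the
timestamp/interval equality of the tachogram is preserved:

* right merge: ``RRj = RR_i + RR_{i+1}`` placed at ``T_{i+1}``; the short
  beat and its timestamp are deleted.
* left merge: ``RRj = RR_i + RR_{i-1}`` placed at ``T_i``; the preceding
  beat and its timestamp are deleted.

A merge is accepted when the merged value lies inside the physiological
band and its relative deviation from both post-merge neighbours stays
within the local variability budget (mean absolute successive relative
difference of the preceding ``lookback`` interval pairs, capped at
``max_deviation``).  When neither merge satisfies the deviation
conditions the branch order below guarantees convergence: deviation
conditions may be dropped as long as the merged value stays under
``rr_max``; if both merges overshoot ``rr_max`` the beat pair is deleted;
if both fit but both deviate, the merge with the smaller total error
wins (ties prefer the right merge, matching the try-right-first order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .rr_model import PhysioBounds, RRSeries

__all__ = [
    "MergeCandidate",
    "FilterAction",
    "FilterReport",
    "local_mean_deviation",
    "evaluate_merge",
    "filter_ectopics",
]


@dataclass(frozen=True)
class MergeCandidate:
    """One evaluated right/left merge for a sub-``rr_min`` interval."""

    kind: Literal["right", "left"]
    merged_value: float
    err_succ: float  # relative deviation vs the post-merge successor
    err_pred: float  # relative deviation vs the post-merge predecessor

    @property
    def err_total(self) -> float:
        return self.err_succ + self.err_pred


@dataclass(frozen=True)
class FilterAction:
    """One decision taken on an out-of-bounds interval.

    ``index`` is the position of the offending beat in the *original*
    series; ``before`` its value; ``after`` the merged value, or None for
    deletions.
    """

    index: int
    action: Literal[
        "delete_long", "right_merge", "left_merge", "delete_pair",
        "forced_right", "forced_left", "least_error_merge", "delete_single",
    ]
    before: float
    after: float | None
    partner: int | None = None  # original index of a consumed neighbour


@dataclass
class FilterReport:
    """Ordered audit trail of every merge/deletion the filter performed."""

    actions: list[FilterAction] = field(default_factory=list)
    passes: int = 0
    unresolved: int = 0  # sub-rr_min intervals remaining after the pass cap

    def to_json(self, path: str | Path) -> None:
        payload = {
            "passes": self.passes,
            "unresolved": self.unresolved,
            "actions": [
                {"index": a.index, "action": a.action,
                 "before": a.before, "after": a.after, "partner": a.partner}
                for a in self.actions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# Merges may cascade (a merged value can itself need repair), so the
# filter sweeps until fixpoint, each sweep examining merge outputs of the
# previous one only.
MAX_PASSES = 5


def _local_deviation(rr: list[float], idx: int, bounds: PhysioBounds) -> float:
    lo = max(1, idx - bounds.lookback)
    terms = [abs(rr[k] - rr[k - 1]) / rr[k - 1] for k in range(lo, idx)]
    if not terms:
        return bounds.max_deviation
    return min(sum(terms) / len(terms), bounds.max_deviation)


def local_mean_deviation(series: RRSeries, index: int,
                         bounds: PhysioBounds | None = None) -> float:
    """Local variability budget at ``index``.

    Mean absolute successive relative difference over the ``lookback``
    interval pairs immediately preceding ``index``, capped at
    ``bounds.max_deviation``; with no preceding pairs the cap itself is
    returned.
    """
    bounds = bounds or PhysioBounds()
    return _local_deviation(list(series.intervals), index, bounds)


def _candidate(rr: list[float], p: int, kind: str) -> MergeCandidate | None:
    n = len(rr)
    if kind == "right":
        if p + 1 >= n:
            return None
        merged = rr[p] + rr[p + 1]
        succ = rr[p + 2] if p + 2 < n else None
        pred = rr[p - 1] if p - 1 >= 0 else None
    else:
        if p - 1 < 0:
            return None
        merged = rr[p] + rr[p - 1]
        succ = rr[p + 1] if p + 1 < n else None
        pred = rr[p - 2] if p - 2 >= 0 else None
    # A missing neighbour at the series edge imposes no constraint.
    err_succ = abs(succ - merged) / merged if succ is not None else 0.0
    err_pred = abs(merged - pred) / pred if pred is not None else 0.0
    return MergeCandidate(kind=kind, merged_value=merged,
                          err_succ=err_succ, err_pred=err_pred)


def evaluate_merge(series: RRSeries, index: int, kind: Literal["right", "left"],
                   bounds: PhysioBounds | None = None) -> MergeCandidate:
    """Evaluate the right or left merge of the sub-``rr_min`` beat at ``index``."""
    bounds = bounds or PhysioBounds()
    cand = _candidate(list(series.intervals), index, kind)
    if cand is None:
        raise IndexError(f"no {kind} neighbour for index {index}")
    return cand


def _filter_pass(ts: list[float], rr: list[float], orig: list[int],
                 bounds: PhysioBounds, actions: list[FilterAction]) -> bool:
    changed = False
    p = 0

    def drop(i: int) -> None:
        del ts[i], rr[i], orig[i]

    while p < len(rr):
        v = rr[p]
        if v >= bounds.rr_min:
            p += 1
            continue

        e10 = _local_deviation(rr, p, bounds)
        right = _candidate(rr, p, "right")
        left = _candidate(rr, p, "left")

        def mergeable(c: MergeCandidate | None) -> bool:
            return c is not None and c.merged_value < bounds.rr_max

        def devs_ok(c: MergeCandidate) -> bool:
            return c.err_succ <= e10 and c.err_pred <= e10

        if mergeable(right) and devs_ok(right):
            chosen, label = right, "right_merge"
        elif mergeable(left) and devs_ok(left):
            chosen, label = left, "left_merge"
        elif not mergeable(right) and not mergeable(left):
            # Both merges would exceed rr_max (or no neighbour exists):
            # the detections around this beat are untrustworthy — delete
            # the beat together with its would-be merge partner.
            if right is not None:
                actions.append(FilterAction(orig[p], "delete_pair", v, None,
                                            partner=orig[p + 1]))
                drop(p + 1)
                drop(p)
            elif left is not None:
                actions.append(FilterAction(orig[p], "delete_pair", v, None,
                                            partner=orig[p - 1]))
                drop(p)
                drop(p - 1)
                p -= 1
            else:
                actions.append(FilterAction(orig[p], "delete_single", v, None))
                drop(p)
            changed = True
            continue
        elif mergeable(right) and not mergeable(left):
            chosen, label = right, "forced_right"
        elif mergeable(left) and not mergeable(right):
            chosen, label = left, "forced_left"
        else:
            # Both merges fit under rr_max but both violate the deviation
            # budget: keep the one with the smaller total error.
            if right.err_total <= left.err_total:
                chosen, label = right, "least_error_merge"
            else:
                chosen, label = left, "least_error_merge"

        if chosen.kind == "right":
            rr[p + 1] = chosen.merged_value
            actions.append(FilterAction(orig[p], label, v, chosen.merged_value,
                                        partner=orig[p + 1]))
            drop(p)
            p += 1  # merged value re-examined only on the next pass
        else:
            rr[p] = chosen.merged_value
            actions.append(FilterAction(orig[p], label, v, chosen.merged_value,
                                        partner=orig[p - 1]))
            drop(p - 1)
            # old p+1 has shifted into position p; continue there
        changed = True
    return changed


def filter_ectopics(series: RRSeries,
                    bounds: PhysioBounds | None = None) -> tuple[RRSeries, FilterReport]:
    """Remove non-physiological intervals from a series.

    Returns the repaired series (long beats deleted, short beats merged)
    and a :class:`FilterReport` recording every decision.  Deletions
    leave timestamp discontinuities (gaps) that the imputation stage
    fills; at every non-gap adjacency the timestamp/interval equality is
    preserved.
    """
    bounds = bounds or PhysioBounds()
    report = FilterReport()
    if len(series) == 0:
        return series, report

    ts = list(series.timestamps)
    rr = list(series.intervals)
    orig = list(range(len(rr)))
    # Long intervals are deleted before any merge is considered, so that
    # merge deviations are never measured against an artifact.
    p = 0
    while p < len(rr):
        if rr[p] > bounds.rr_max:
            report.actions.append(
                FilterAction(orig[p], "delete_long", rr[p], None))
            del ts[p], rr[p], orig[p]
        else:
            p += 1
    for _ in range(MAX_PASSES):
        report.passes += 1
        if not _filter_pass(ts, rr, orig, bounds, report.actions):
            break
    report.unresolved = sum(1 for v in rr if v < bounds.rr_min)
    out = RRSeries(timestamps=np.asarray(ts), intervals=np.asarray(rr),
                   label=series.label)
    return out, report
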