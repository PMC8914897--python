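"""Independent rule-table oracle for the ectopic filter.

A deliberately plain, brute-force transcription of the filtering rules,
written against (timestamp, interval) pair lists and sharing no code
with the production implementation.  Used to cross-check
``hrvdvc.ectopic_filtering.filter_ectopics`` exhaustively on small
series.
"""

from __future__ import annotations


def _budget(values: list[float], i: int, lookback: int, cap: float) -> float:
    terms = []
    for k in range(max(1, i - lookback), i):
        terms.append(abs(values[k] - values[k - 1]) / values[k - 1])
    if not terms:
        return cap
    return min(cap, sum(terms) / len(terms))


def _deviations(merged: float, succ: float | None, pred: float | None):
    err_s = 0.0 if succ is None else abs(succ - merged) / merged
    err_p = 0.0 if pred is None else abs(merged - pred) / pred
    return err_s, err_p


def _option(values: list[float], i: int, side: str):
    n = len(values)
    if side == "right":
        if i + 1 >= n:
            return None
        merged = values[i] + values[i + 1]
        succ = values[i + 2] if i + 2 < n else None
        pred = values[i - 1] if i - 1 >= 0 else None
    else:
        if i - 1 < 0:
            return None
        merged = values[i] + values[i - 1]
        succ = values[i + 1] if i + 1 < n else None
        pred = values[i - 2] if i - 2 >= 0 else None
    err_s, err_p = _deviations(merged, succ, pred)
    return {"merged": merged, "err_s": err_s, "err_p": err_p,
            "total": err_s + err_p}


def oracle_filter(timestamps, intervals, rr_min=0.3, rr_max=1.3,
                  cap=0.4, lookback=10, max_passes=5):
    """Return (timestamps, intervals) after applying the decision table."""
    pairs = [(float(t), float(v)) for t, v in zip(timestamps, intervals)]
    # All long intervals go first, before any merge is evaluated.
    pairs = [(t, v) for (t, v) in pairs if v <= rr_max]

    for _ in range(max_passes):
        changed = False
        i = 0
        while i < len(pairs):
            v = pairs[i][1]
            if v >= rr_min:
                i += 1
                continue
            rr = [p[1] for p in pairs]
            e10 = _budget(rr, i, lookback, cap)
            right = _option(rr, i, "right")
            left = _option(rr, i, "left")
            r_ok = right is not None and right["merged"] < rr_max
            l_ok = left is not None and left["merged"] < rr_max
            r_dev = right is not None and right["err_s"] <= e10 and right["err_p"] <= e10
            l_dev = left is not None and left["err_s"] <= e10 and left["err_p"] <= e10

            if r_ok and r_dev:
                choice = "right"
            elif l_ok and l_dev:
                choice = "left"
            elif not r_ok and not l_ok:
                choice = "delete"
            elif r_ok:
                choice = "right"
            elif l_ok:
                choice = "left"
            else:  # unreachable; both candidates None handled by delete
                choice = "delete"
            if r_ok and l_ok and not r_dev and not l_dev:
                choice = "right" if right["total"] <= left["total"] else "left"

            if choice == "right":
                t_next = pairs[i + 1][0]
                pairs[i + 1] = (t_next, right["merged"])
                del pairs[i]
                i += 1  # the merged value waits for the next pass
            elif choice == "left":
                pairs[i] = (pairs[i][0], left["merged"])
                del pairs[i - 1]
                # the element after the merged one has shifted into i
            else:  # delete the beat and its would-be merge partner
                if right is not None:
                    del pairs[i + 1]
                    del pairs[i]
                elif left is not None:
                    del pairs[i]
                    del pairs[i - 1]
                    i -= 1
                else:
                    del pairs[i]
            changed = True
        if not changed:
            break
    return [p[0] for p in pairs], [p[1] for p in pairs]
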