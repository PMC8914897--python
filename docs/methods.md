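# Methods

This note documents the models and procedures implemented in `hrvdvc`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic experiments do and do not show.

## The tachogram model and its invariant

An RR series is stored as `(timestamps, intervals)` with each interval carried
by the timestamp of the beat that ends it. The structural invariant is
`RR_i = T_i − T_{i−1}` at every adjacency that is not a gap; `check_consistency`
verifies it to 1e−9 s (float noise only; every repair operation is exact
arithmetic on the same quantities). An adjacency whose timestamp difference
exceeds `rr_max` is classified as a gap — lost beats — rather than an
inconsistency. The threshold choice is an interpretation: no minimum gap span
is defined by the procedure itself, and `rr_max` is the largest jump a single
legitimate beat could produce.

Units are seconds internally; readers accept milliseconds and divide on
ingest; features are reported in milliseconds as is conventional.

## Physiological bounds

`PhysioBounds` collects the tunables:

| parameter | default | meaning |
|---|---|---|
| `rr_min` | 0.3 s | shortest plausible inter-beat interval (200 bpm) |
| `rr_max` | 1.3 s | longest plausible interval (~46 bpm) |
| `max_deviation` | 0.4 | cap on the local variability budget (≈ twice the largest normal successive swing) |
| `lookback` | 10 | preceding interval pairs used for local statistics |

The local variability budget E is the mean absolute successive relative
difference over the `lookback` pairs immediately *preceding* the beat under
repair, capped at `max_deviation`; with no preceding pairs the cap itself is
used. The lookback is backward even though a printed index form of the sum
can be read as forward: every other use of the statistic (gap fitting,
gap-size estimation) is explicitly "the last 10 values", and a backward
window is the only causal choice for streaming repair.

## Ectopic filtering

Long intervals (> `rr_max`) are deleted first, in a dedicated sweep, so that
merge decisions are never evaluated against an artifact value; the deletions
leave timestamp gaps for the imputation stage. Short intervals (< `rr_min`)
are then resolved left-to-right by the branch order described in the README.
Implementation details that the branch order does not fix by itself:

- **Cascades.** A merged value can itself be short; it is re-examined only on
  a subsequent full sweep (fixpoint, at most 5 sweeps — two consecutive
  sub-`rr_min` detections resolve in two). A sub-minimum value surviving all
  sweeps is counted in `FilterReport.unresolved`; it does not occur on any
  generated corpus.
- **Bounds in branch conditions.** Conditions compare the merged value to
  `rr_max` only; a merged value still below `rr_min` (two stacked artifacts)
  is accepted and repaired on the next sweep rather than rejected outright.
- **Edges.** A short beat at the series boundary has one candidate; if that
  candidate exceeds `rr_max` the beat and its would-be partner are deleted,
  mirroring the interior delete-pair branch. A missing successor or
  predecessor imposes no deviation constraint.
- **Ties.** Equal total errors prefer the right merge, matching the
  try-right-first order.

Merges conserve the interval sum and the spanned time exactly, so the
consistency invariant survives by construction. The filter is validated
exhaustively against an independently coded rule-table oracle on all ~56k
series of length ≤ 6 over a 6-value interval grid.

## DVC gap imputation

Per gap, `N(μ, σ²)` is fitted (sample SD, n−1) on up to `lookback` intervals
ending at the gap start; the deviation budget is frozen from the same pre-gap
data. Filling proceeds backward from `T1 = T_end − RR_end`; each draw is
rejection-sampled (cap 1000, then clamped into
`[max(rr_min, μ−2σ), min(rr_max, μ+2σ)]`) against the bounds and the budget
relative to its already-inserted successor — the predecessor does not exist
yet; the closing interval is checked against both neighbours. On a failed
closing, the last two draws are discarded; every four failures the budget is
relaxed by +0.05 absolute (the package reads "increased by 5%" as absolute,
consistent with the other fractions). Degenerate cases and their handling:

- **Infeasible sliver.** If `span − RR_end ≤ rr_min` no in-bounds tiling
  exists. `impute_dvc` deletes the beat immediately preceding the gap, which
  always restores feasibility (the residual grows by at least `rr_min`); a
  gap that reaches the series head this way is left unfilled. Both events are
  logged per gap.
- **Degenerate fits.** With σ ≈ 0 the closing-retry loop can regenerate the
  same draw forever; after 24 failed closing attempts sampling falls back to
  a uniform draw over `[rr_min, rr_max]`, preserving bounds and termination
  at the cost of distribution fidelity (logged).
- **Reproducibility.** Each gap consumes an independent substream derived
  from `(seed, gap ordinal)`, so fills are deterministic and
  order-insensitive.

**Known bias.** The deviation budget truncates each draw to a window around
its successor (`x ∈ [s/(1+c), s/(1−c)]`), which is asymmetric; when the
budget c is small (very regular pre-gap data, c ≈ 0.1) the inserted-interval
mean drifts a few milliseconds above μ. With a budget near or above ~0.25 the
truncation rarely binds and the inserted mean recovers μ to well within
`3σ/√n`. This is a property of the method, not an implementation defect, and
the distribution-recovery experiments use pre-gap data in the mild-truncation
regime.

## Baseline interpolation

For each missing region, `N = floor(span / mean RR over the last lookback
intervals)` placeholder timestamps are spread uniformly and valued by a
global 1-D interpolant (interval vs timestamp): `np.interp`,
`PchipInterpolator`, or `CubicSpline` with not-a-knot ends ("spline" in the
most common sense; documented so results reproduce across ecosystems). A
quotient a float-rounding hair under an integer is snapped up before
flooring. Besides long gaps, baselines also fill *short holes* — adjacencies
whose interval does not account for the timestamp difference, as left by
deleting a single artifact beat — since interpolation pipelines replace every
value they delete. No consistency repair is performed and out-of-band
interpolant values are kept (flagged by `bounds_audit`, never removed):
the time-dependence loss of these methods is the phenomenon under study.
Fewer than 2 (linear) or 4 (pchip/spline) support points falls back to
linear, logged. `deletion` removes out-of-bounds intervals and fills nothing.

## Features

Sliding windows, default 300 s long with a 60 s slide anchored at the start
of the first interval; a 15-min series yields 11 windows. Per window: SDNN
(sample SD), RMSSD (mean over the N−1 squared successive differences, as the
denominator is printed in the field's common form), NN50/pNN50 (strictly
> 50 ms), Poincaré SD1/SD2 via the standard ellipse identities
`SD1² = Var(ΔRR)/2`, `SD2² = 2·Var(RR) − Var(ΔRR)/2` (sample variances;
negative radicands from float noise clamp to zero), and LF/HF powers from a
Welch periodogram of the tachogram cubic-resampled at 8 Hz, mean-detrended,
with segments up to two minutes; LF integrates 0.04–0.15 Hz and requires two
minutes of data, HF 0.15–0.4 Hz and one minute. ULF/VLF need recordings far
beyond a sliding window and are not computed; no wavelet variant is provided.
Undefined features are NaN throughout. Feature engineering expands every
unordered pair of base columns into a product and one quotient (numerator
first in the documented column order, so `rmssd_div_sdnn` exists); zero
denominators give NaN.

## Synthetic data

The generator lays beats down sequentially from
`RR(t) = mean + lf_amp·sin(2π·0.1t) + hf_amp·sin(2π·0.25t) + jitter`, with
white Gaussian jitter topping the sinusoidal variance up to a target SDNN —
consistent by construction, in the spirit of integral-pulse-frequency-
modulation models. Presets: relax (mean 0.92 s, SDNN 65 ms, HF-dominant) and
stress (mean 0.78 s, SDNN 35 ms, LF-shifted), reflecting the standard acute-
stress signature (shorter intervals, suppressed overall and respiratory
variability). The means are deliberately high enough that twice the mean
clearly exceeds `rr_max`: a single missed beat then always surfaces as a
deletable long interval. With faster baseline heart rates a missed beat can
hide below a fixed 1.3 s bound and no interval-based filter can recover it —
a structural limit of fixed physiological bounds worth knowing about.

Degradation deletes a uniform random `round(n·pct/100)` of beats (optionally
in contiguous bursts) and corrupts a disjoint set with ectopics. Deletion is
detector-realistic: the surviving beat after a deleted run carries the
peak-to-peak time difference as its interval, exactly as re-deriving
intervals from the remaining peaks would; the plan records the overwritten
seam values so deletion is exactly invertible. The default ectopic model
splits an interval by a spurious extra peak into a sub-`rr_min` part and a
remainder (fully consistent; the artifact mechanism the merge rule inverts
exactly); a `replace` mode overwrites the value in place, destroying the
information — under that model the merge rule necessarily leaves paired
outliers, which is visible in the benchmark.

What the generator does **not** emulate: autocorrelated (1/f) beat-to-beat
dynamics — its jitter is white, so RMSSD ≈ √2·SDNN, unlike real data where
successive differences are much smaller than overall variability;
respiratory-rate drift; transients between conditions; and detector noise in
the timestamps themselves. Passing tests therefore demonstrate the
*invariants* (bounds, consistency, span tiling, determinism) and the
*relative ordering* of reconstruction methods under these conditions, not
absolute feature accuracy on real recordings.

## Benchmark design

Corpus: 10 subjects per condition, 10-min recordings, per-subject parameter
jitter, and a small intrinsic artifact load (up to 1% missing, 2% ectopic) —
real training data are never pristine, and a classifier fitted to perfectly
clean features is brittle to any artifact-driven inflation. Features from the
raw originals are split 80/20 stratified; a random forest (entropy criterion,
max-features 0.6, min-samples-split 3, 500 trees — a tuned preset; a 10-fold
grid search over min-samples-split/leaf, n-estimators and max-features is
available behind `tune=True`) is fitted once on the training windows.
Engineered columns more than 20% undefined on the originals are dropped;
remaining NaNs are filled with training medians. Each degradation level
degrades every series once; all methods reconstruct the *same* degraded
signal, and the same validation windows (series, window-start pairs present
in every variant) are scored for every method, so no training data leaks and
scores are directly comparable. F1 uses stress as the positive class.

DVC reconstructs with the full filter + imputation; the interpolation
baselines delete only the long intervals (that deletion is what surfaces the
gaps they fill) and leave sub-`rr_min` values in place — interpolation
pipelines replace missing data, they do not repair present-but-wrong beats.
At 5–35% missing with 5% ectopic, DVC's validation F1 stays approximately
flat while linear/pchip decline; the acceptance script prints the measured
values. Problem sizes (series length, corpus size, seed counts) were chosen
so the full suite and the acceptance script each complete in well under a
minute of compute while leaving the orderings stable across seeds.

## Limitations

- The merge rule assumes the sub-`rr_min` interval is an extra detection; on
  true premature beats followed by compensatory pauses it still produces an
  in-bounds value but not the physiologically "correct" one.
- Gap filling preserves the local distribution, not oscillatory structure:
  spectral features computed across heavily imputed stretches lose LF/HF
  modulation and gain broadband power.
- The consistency invariant can only be guaranteed for corruption that
  preserves the information needed to restore it; value-replacement ectopics
  (`ectopic_mode="replace"`) leave a few adjacencies whose repair is
  necessarily approximate.
- Fixed bounds (0.3/1.3 s) are not adaptive to the subject's heart rate; see
  the note on missed beats above.
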