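# Methods

## The estimator

A tap log is a strictly increasing sequence of timestamps, one tap per
inhalation. The estimator maintains the `z` most recent inter-tap intervals.
After every tap from the `(z+1)`-th onward it computes the set's median
interval `Ĩ` (for even `z`, the mean of the two middle order statistics) and
the consistency

    C = 100 · max_i |I_i − Ĩ| / Ĩ   [%].

The set is accepted when `C ≤ Th_C` — the comparison is inclusive — and the
implied rate `60/Ĩ` lies within the reportable range of 2–140 breaths/min; an
accepted set outside that range is treated like an inconsistent one and
tapping continues. With the threshold disabled, the first full set is
accepted (so exactly `z+1` taps complete a measurement). Efficiency `E` is
the time from the first tap to the accepting tap. Taps more than 60 s after
the first tap are never consumed; if no set is accepted by then the
measurement fails, `E` is recorded as 60 s, and the completion rate CR is
reduced. `C` is compared to `Th_C` in exact floating-point arithmetic, with
no rounding.

The streaming implementation (incremental sorted window) is cross-checked in
the test suite against an independent brute-force search over all windows;
the offline grid replay in `rrtap.evaluate` is that exhaustive enumeration,
vectorized, and is itself checked cell-by-cell against the streaming path.

## Metrics

- **NRMSE** `= 100 · sqrt(mean(((RR − RR_ref)/RR_ref)²))`, computed over
  completed observations only. The normalization is per observation, which
  makes the percentage directly interpretable as relative RMS error (x% at a
  reference of 40 breaths/min ↔ 0.4·x breaths/min). The published source of
  this statistic renders the formula as an image; the per-observation form is
  inferred from the printed percent-to-absolute conversions and is stated
  here as this package's definition.
- **Efficiency statistics** (median, mean, 95th percentile with linear
  interpolation between order statistics) include failed measurements at the
  60 s cap, so accuracy failures are penalized through time, not excluded.
- **Bland–Altman**: differences estimated − reference; bias is their mean,
  SD the sample standard deviation (ddof=1), limits of agreement bias ± 2·SD.
- **Sensitivity grid**: every (z, Th_C) cell for z = 2..15 and Th_C = 2..30%
  in 1-point steps, plus the threshold-disabled column and an "all taps"
  reference (60 / median of all intervals in the 60 s log) whose NRMSE is the
  asymptote the grid approaches at large z.
- **Regression summary**: descriptive OLS of NRMSE and median E on (z, Th_C)
  over grid cells, reported with coefficients and R². It quantifies the
  direction and rough magnitude of the trends only; no inferential claims are
  made from it, and cells with undefined NRMSE are dropped.

## Cost optimization

The accuracy–efficiency trade-off is scored by

    J(z, Th_C) = w · NRMSE + E_median + E_95,   w = 15 s / 4 % = 3.75

so that performance at the two acceptability limits — 15 s of measurement
time, 4% error — contributes equally. Both limits and `w` are configurable
(`CostConfig`). CR enters only through the E = 60 s penalty that failures
already carry. A cell where nothing completes has infinite cost.

Cross-validation: for each video, two observations go to each of 15 bins
(uniformly at random, seeded); each bin serves once as test set. Per fold the
training-cost-minimizing cell is recorded (ties resolved to lower z, then
lower Th_C); the selection is the modal per-fold minimizer, with ties broken
by lower mean training cost, then lower z, then lower Th_C — fully
deterministic given the seed. The selected configuration's per-fold test
NRMSE is compared to the threshold-free z = 4 baseline with a two-sided
paired t-test at α = 0.05. When the fold differences have zero variance the
t statistic is undefined: the result is flagged degenerate, "not significant"
if the constant difference is zero and "significant" otherwise. Whether the
source analysis summed or averaged the two efficiency terms, and its exact
`w`, are not recoverable from the text; the sum with `w = 3.75` is this
package's documented choice and a one-line swap in `CostConfig`.

## The synthetic study

`simulate_taps` draws breath onsets from a Gamma renewal process with mean
interval `60/rr_true` and coefficient of variation `breath_cv` (Gamma for
positive support and direct CV parameterization; the choice of family is a
modeling convenience, not an empirical claim). Each breath is tapped with
independent Gaussian jitter (`tap_jitter_sd`); with probability `p_missed` a
breath is not tapped, merging two intervals; with probability `p_extra` per
gap a spurious tap splits an interval at a uniform position. Jitter is
resampled on the rare strict-ordering violation. Times are shifted so the
first tap is at 0 and truncated 60 s later. Everything is reproducible from
the model seed.

`simulate_study` emulates the reference design: 30 observers × 10 recordings
with reference rates (56, 33, 59, 47, 51, 30, 38, 24, 17, 17) breaths/min.
The first five recordings are mechanically ventilated subjects and are
simulated with `breath_cv = 0.03` (near-periodic); the last five breathe
spontaneously, `breath_cv = 0.10`. Observer skill varies between subjects
via a lognormal multiplier (σ = 0.3, unit mean) on `tap_jitter_sd`; defaults
`tap_jitter_sd = 0.05 s`, `p_missed = 0.05`, `p_extra = 0.02`. These
magnitudes are assumptions chosen once as physiologically and motorically
plausible (breath-interval CV of a few percent under controlled ventilation,
~10% spontaneous; tens of milliseconds of tapping jitter) — they are not
measured values. A single study seed spawns per-subject substreams, so any
subject subset reproduces independently; video order is randomized per
subject.

What the simulator does **not** model: shared breath tracks across observers
(each log draws its own breathing realization, while real observers watched
identical videos), periodic breathing or apnea, observer learning or fatigue,
and reaction-time asymmetry (jitter is zero-mean). Consequently, passing
tests demonstrate correctness of the algorithms and the qualitative
trade-off shapes — accuracy improving with z and with tighter thresholds,
CR collapsing at tight Th_C/large z, the consistency filter significantly
lowering NRMSE when aberrant taps are present — not the exact operating
point a human study would select.

## Numerical and design notes

- Even-`z` median: mean of the two middle order statistics (standard
  convention; matters because z = 4 is the configuration of interest).
- The 60 s cap fires at the first tap that would exceed it, never mid-gap
  (E is defined tap-to-tap); a tap exactly at the cap (within 1e-12 slack
  for float accumulation) is consumed.
- 95th percentiles use linear interpolation so results are dialect-stable
  across environments.
- CR is *exactly* monotone in Th_C at fixed z (an accepted set stays
  accepted under a looser threshold). It is **not** exactly monotone in z on
  a fixed log set: the even/odd median parity can let a larger window pass
  where every smaller one fails. In z, the decline of CR is a study-level
  trend and is tested as such.
- On the default synthetic study the cross-validated cost optimum sits at
  z = 3 with a loose threshold (Th_C ≈ 22–30%): the simulated tapping has
  heavier efficiency tails (poor tappers on fast videos) than real
  observations, so the E_95 term pushes away from tight thresholds. The
  selection never falls to the fastest z = 2 corner, and its NRMSE still
  beats the threshold-free baseline.
- Tap times serialize at millisecond precision (finer than any touch-screen
  event clock); round-trips are exact for logs at that precision.

## Problem sizes

Defaults throughout are the full study scale: 300 logs, the full 14 × 29
grid plus the disabled column, 15 folds, and 20-seed Monte-Carlo repetitions
in the qualitative tests — the entire suite and the acceptance script run in
well under a minute each on one core, so nothing is scaled down.
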