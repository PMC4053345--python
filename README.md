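# rrtap

Tap-interval respiratory-rate estimation with consistency-based quality
control.

The recommended way to measure respiratory rate (RR) — counting breaths for a
full 60 s — is slow and error-prone in busy clinical settings, particularly
when screening children for fast breathing. An alternative is to tap a touch
screen once per inhalation and estimate the rate from the inter-tap
intervals:

    RR = 60 / median(I_1, ..., I_z)            [breaths/min]

where `I_1..I_z` are the `z` most recent inter-tap intervals in seconds. The
quality of a set is its **consistency**

    C = 100 · max_i |I_i − Ĩ| / Ĩ              [%],  Ĩ = median interval

and a rate is only reported once `C ≤ Th_C`, a consistency threshold;
otherwise the oldest interval is dropped, the next tap appended, and the new
set re-evaluated. `z + 1` taps is the minimum to complete a measurement, and
a measurement that does not complete within 60 s of the first tap fails.
This rejects aberrant taps (missed breaths, double taps) on the fly, and
typically reports a rate in well under 60 s.

`rrtap` implements this streaming estimator together with the machinery to
characterize it:

- **`rrtap.core`** — interval extraction, median, consistency, and the
  streaming earliest-acceptance algorithm.
- **`rrtap.simulate`** — a seeded generator of synthetic tap logs (Gamma
  renewal breathing, Gaussian tap jitter, missed/extra taps) and of whole
  studies: by default 30 simulated observers × 10 reference recordings
  spanning 17–59 breaths/min.
- **`rrtap.evaluate`** — accuracy as NRMSE (percent relative RMS error),
  efficiency E (time from first tap to report, capped at 60 s on failure),
  completion rate CR, Bland–Altman agreement, the (z, Th_C) sensitivity grid,
  and a descriptive linear-trend summary.
- **`rrtap.optimize`** — trade-off optimization of (z, Th_C) by minimizing
  `J = w·NRMSE + E_median + E_95` (w = 3.75 s/% so that the 15 s and 4%
  acceptability limits weigh equally) under 15-fold cross-validation with
  per-video binning, plus a paired t-test against the threshold-free
  estimator.
- **`rrtap.io` / `rrtap.cli`** — long-format CSV/JSON tap-log serialization
  and the `rrtap` command with `simulate`, `estimate`, `grid`, `optimize`
  and `report` subcommands.

## Worked example

Simulate a small study and estimate each log at z = 4, Th_C = 13%:

```text
$ rrtap simulate --subjects 2 --seed 7 --out demo.csv
wrote 20 tap logs to demo.csv

$ rrtap estimate demo.csv --z 4 --thc 13
subject_id,video_id,rr_ref,rr,efficiency_s,taps_used,completed
S00,V09,17,17.86,13.432,5,True
S00,V06,38,38.52,9.324,8,True
S00,V02,59,59.73,4.020,5,True
S00,V01,33,32.54,7.471,5,True
...
```

The first log's observer tapped along with a subject breathing at
17 breaths/min; the estimator accepted the first full set of 4 intervals
(5 taps) after 13.4 s and reported 17.86 breaths/min. For the 38 breaths/min
recording, the first sets were inconsistent (C > 13%), so three extra taps
were consumed before a set passed — the consistency test trading a little
time for accuracy.

The full pipeline on a 300-observation study:

```python
from rrtap import StudyDesign, simulate_study, replay_matrix, crossvalidate

logs = simulate_study(StudyDesign(seed=1))        # 30 subjects x 10 videos
cell = replay_matrix(logs).summary(4, 13.0)
print(cell.nrmse, cell.e_median, cell.cr)         # 4.25 %, 9.85 s, 99.3 %

result = crossvalidate(logs, seed=1)              # 15-fold CV optimization
print(result.selected)                            # (3, 29.0)
```

At (z=4, Th_C=13%) the simulated study yields an NRMSE of 4.25% — at a
reference rate of 40 breaths/min, roughly 1.7 breaths/min of RMS error —
with 99.3% of measurements completing, at a median of 9.8 s instead of the
conventional 60 s. The cross-validation selects the cheapest configuration
under the cost `J`; on synthetic data the optimum sits at a small set size
with a loose threshold, and its per-fold NRMSE is significantly lower than
the threshold-free baseline's.

## Limitations

The synthetic observers are a model, not recorded humans; see
`docs/methods.md` for the generative assumptions, what they emulate, and
what conclusions they do and do not support.
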