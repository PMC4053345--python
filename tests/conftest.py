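"""Shared fixtures and the independent brute-force oracle.

The oracle re-derives the streaming estimator's answer by exhaustively
enumerating every window of z consecutive intervals with numpy and taking the
earliest acceptable one; it shares no code with the incremental streaming
implementation in ``rrtap.core``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pytest

from rrtap import EstimatorConfig, TapLog


def brute_force_estimate(log: TapLog, config: EstimatorConfig):
    """Earliest-valid-window search over all windows; independent oracle.

    Returns (completed, rr, efficiency) with the same acceptance rules as the
    streaming estimator: inclusive threshold, reportable-rate range, 60 s cap
    measured from the first tap.
    """
    t = np.asarray(log.tap_times, dtype=float)
    if t.size:
        t = t[t - t[0] <= config.max_duration + 1e-12]
    z = config.z
    if t.size < z + 1:
        return False, None, config.max_duration
    iv = np.diff(t)
    for k in range(z, iv.size + 1):
        w = iv[k - z : k]
        med = float(np.median(w))
        c = 100.0 * float(np.max(np.abs(w - med))) / med
        rr = 60.0 / med
        if (config.th_c is None or c <= config.th_c) and config.rr_min <= rr <= config.rr_max:
            return True, rr, float(t[k] - t[0])
    return False, None, config.max_duration


def random_tap_log(rng: np.random.Generator, min_taps: int = 6, max_taps: int = 45) -> TapLog:
    """A rough random tap log: lognormal intervals with occasional outliers."""
    n = int(rng.integers(min_taps, max_taps + 1))
    iv = rng.lognormal(np.log(1.5), 0.25, n - 1)
    outliers = rng.random(n - 1) < 0.1
    iv[outliers] *= rng.uniform(2.0, 4.0, outliers.sum())
    taps = np.concatenate([[0.0], np.cumsum(iv)])
    return TapLog("rand", "rand", tuple(taps.tolist()), rr_ref=40.0)


@pytest.fixture
def regular_log() -> TapLog:
    """Constant 1.5 s spacing: RR 40, zero consistency everywhere."""
    return TapLog("s1", "v1", (0.0, 1.5, 3.0, 4.5, 6.0), rr_ref=40.0)


@pytest.fixture
def outlier_log() -> TapLog:
    """Early aberrant intervals (3.0 s, 4.0 s) followed by clean 1 s tapping."""
    return TapLog(
        "s1", "v2", (0.0, 1.0, 4.0, 5.0, 9.0, 10.0, 11.0, 12.0, 13.0), rr_ref=60.0
    )
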