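"""Tap-interval respiratory-rate estimation.

Respiratory rate (RR) is estimated from the times at which an observer taps a
screen once per breath: RR = 60 s divided by the median of a set of ``z``
consecutive inter-tap intervals.  The quality of a set is summarised by its
*consistency* ``C``, the maximum percentage absolute deviation of any interval
in the set from the set's median.  A set is reported only when ``C`` is at or
below a threshold ``Th_C``; otherwise the earliest interval is discarded, the
next tap appended, and the new set re-evaluated — a streaming
earliest-acceptance scheme that rejects aberrant taps on the fly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "TapLog",
    "IntervalSet",
    "EstimatorConfig",
    "RREstimate",
    "intervals_from_taps",
    "median_interval",
    "consistency",
    "rr_from_median",
    "evaluate_set",
    "estimate_streaming",
]

#: slack for the 60 s cap comparison so that a tap landing exactly on the cap
#: (up to float rounding) is still consumed
_CAP_EPS = 1e-12


@dataclass(frozen=True)
class TapLog:
    """One observation: an ordered tap sequence plus its reference RR.

    Parameters
    ----------
    subject_id, video_id
        Opaque identifiers of the observer and the observed recording.
    tap_times
        Tap timestamps in seconds from session start, strictly increasing.
    rr_ref
        Reference respiratory rate in breaths/min (expert observation).
    """

    subject_id: str
    video_id: str
    tap_times: tuple[float, ...]
    rr_ref: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tap_times", tuple(float(t) for t in self.tap_times))
        for a, b in zip(self.tap_times, self.tap_times[1:]):
            if not b > a:
                raise ValueError(
                    f"tap_times must be strictly increasing "
                    f"(log {self.subject_id}/{self.video_id}: {a} followed by {b})"
                )
        if not self.rr_ref > 0:
            raise ValueError(f"rr_ref must be positive, got {self.rr_ref}")

    @property
    def n_taps(self) -> int:
        return len(self.tap_times)


@dataclass(frozen=True)
class IntervalSet:
    """A set of ``z`` inter-tap intervals with its median and consistency."""

    intervals: tuple[float, ...]
    median_interval: float
    consistency: float

    @classmethod
    def from_intervals(cls, intervals: Sequence[float]) -> "IntervalSet":
        ivs = tuple(float(v) for v in intervals)
        return cls(ivs, median_interval(ivs), consistency(ivs))


@dataclass(frozen=True)
class EstimatorConfig:
    """Estimator parameters.

    ``th_c`` is the consistency threshold in percent; ``None`` disables the
    consistency test (the first full set is then accepted).  ``rr_min`` and
    ``rr_max`` bound the reportable rate (the app's 2–140 breaths/min range);
    ``max_duration`` caps the measurement at 60 s from the first tap.
    """

    z: int = 4
    th_c: Optional[float] = 13.0
    rr_min: float = 2.0
    rr_max: float = 140.0
    max_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.z < 2:
            raise ValueError(f"z must be >= 2, got {self.z}")
        if self.th_c is not None and not self.th_c > 0:
            raise ValueError(f"th_c must be positive when enabled, got {self.th_c}")
        if not self.rr_min < self.rr_max:
            raise ValueError("rr_min must be < rr_max")
        if not self.max_duration > 0:
            raise ValueError("max_duration must be positive")


@dataclass(frozen=True)
class RREstimate:
    """A reported rate with its efficiency (time-to-report).

    ``efficiency`` is the time in seconds from the first tap to the accepting
    tap; on failure it equals the 60 s cap and ``rr`` is ``None``.
    """

    rr: Optional[float]
    efficiency: float
    taps_used: int
    accepted_set: Optional[IntervalSet]
    completed: bool


def intervals_from_taps(tap_times: Sequence[float]) -> list[float]:
    """Successive differences of a strictly increasing tap sequence."""
    if len(tap_times) < 2:
        raise ValueError(f"need at least 2 taps, got {len(tap_times)}")
    out = []
    for a, b in zip(tap_times, tap_times[1:]):
        if not b > a:
            raise ValueError(f"tap times not strictly increasing: {a} then {b}")
        out.append(b - a)
    return out


def median_interval(intervals: Sequence[float]) -> float:
    """Median interval: middle order statistic, or the mean of the two middle
    order statistics for an even number of intervals."""
    n = len(intervals)
    if n == 0:
        raise ValueError("cannot take the median of an empty interval set")
    srt = sorted(intervals)
    if n % 2:
        return srt[n // 2]
    return 0.5 * (srt[n // 2 - 1] + srt[n // 2])


def consistency(intervals: Sequence[float]) -> float:
    """Consistency C: maximum percentage absolute deviation from the median.

    ``C = 100 * max_i |I_i - med| / med``.  Zero iff all intervals are equal.
    """
    if len(intervals) < 2:
        raise ValueError("consistency needs at least 2 intervals")
    med = median_interval(intervals)
    return 100.0 * max(abs(v - med) for v in intervals) / med


def rr_from_median(med: float) -> float:
    """Respiratory rate in breaths/min: 60 s divided by the median interval."""
    if not med > 0:
        raise ValueError(f"median interval must be positive, got {med}")
    return 60.0 / med


def evaluate_set(
    intervals: Sequence[float], th_c: Optional[float]
) -> tuple[bool, IntervalSet]:
    """Accept or reject one set of intervals against the consistency threshold.

    The comparison is inclusive: a set with ``C == th_c`` is accepted.  With
    ``th_c`` disabled (``None``) every set is accepted.
    """
    iset = IntervalSet.from_intervals(intervals)
    accepted = th_c is None or iset.consistency <= th_c
    return accepted, iset


def estimate_streaming(log: TapLog, config: EstimatorConfig) -> RREstimate:
    """Run the streaming accept/reject algorithm over one tap log.

    Taps are consumed in time order.  Once ``z`` intervals exist, the set of
    the ``z`` most recent intervals is evaluated after every new tap; the
    first set with ``C <= th_c`` (or any full set when ``th_c`` is disabled)
    whose rate falls within ``[rr_min, rr_max]`` is reported.  Taps later than
    ``max_duration`` after the first tap are never consumed; if no set is
    accepted, the estimate is incomplete with efficiency equal to the cap.
    """
    z = config.z
    times = log.tap_times
    if not times:
        return RREstimate(None, config.max_duration, 0, None, False)
    t0 = times[0]
    window: list[float] = []  # last z intervals, arrival order
    srt: list[float] = []  # the same values, kept sorted
    prev = t0
    consumed = 1
    for t in times[1:]:
        if t - t0 > config.max_duration + _CAP_EPS:
            break
        consumed += 1
        iv = t - prev
        prev = t
        window.append(iv)
        bisect.insort(srt, iv)
        if len(window) > z:
            oldest = window.pop(0)
            del srt[bisect.bisect_left(srt, oldest)]
        if len(window) == z:
            med = srt[z // 2] if z % 2 else 0.5 * (srt[z // 2 - 1] + srt[z // 2])
            c = 100.0 * max(srt[-1] - med, med - srt[0]) / med
            if config.th_c is not None and c > config.th_c:
                continue
            rr = 60.0 / med
            if not (config.rr_min <= rr <= config.rr_max):
                continue
            return RREstimate(
                rr=rr,
                efficiency=t - t0,
                taps_used=consumed,
                accepted_set=IntervalSet(tuple(window), med, c),
                completed=True,
            )
    return RREstimate(None, config.max_duration, consumed, None, False)
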