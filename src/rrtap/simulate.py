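"""Seeded synthetic tap-stream generation.

Emulates an observer tapping a touch screen once per inhalation while watching
a subject breathe for 60 s.  Breath onsets follow a Gamma renewal process
(mean interval ``60 / rr_true``, coefficient of variation ``breath_cv``);
taps are the breath onsets perturbed by Gaussian motor jitter, with breaths
occasionally missed (merging two intervals) and spurious extra taps
occasionally inserted (splitting an interval).  These two aberrations are the
minimal taxonomy producing the interval outliers the consistency test is
designed to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import TapLog

__all__ = [
    "TapperModel",
    "StudyDesign",
    "simulate_taps",
    "simulate_study",
    "TABLE_RRS",
    "TABLE_BREATH_CVS",
]

#: Reference rates (breaths/min) of the ten standard videos used as the
#: default study conditions; they span 17-59 breaths/min.  The first five are
#: controlled (mechanical) ventilation, the last five spontaneous breathing.
TABLE_RRS: tuple[float, ...] = (56.0, 33.0, 59.0, 47.0, 51.0, 30.0, 38.0, 24.0, 17.0, 17.0)

#: Default breath-interval coefficient of variation per video: controlled
#: ventilation is near-periodic, spontaneous breathing varies more.
TABLE_BREATH_CVS: tuple[float, ...] = (0.03,) * 5 + (0.10,) * 5


@dataclass(frozen=True)
class TapperModel:
    """Generative parameters for one observer tapping along with one subject.

    Parameters
    ----------
    rr_true
        The subject's true respiratory rate, breaths/min.
    breath_cv
        Coefficient of variation of the breath-to-breath interval (unitless).
        0 gives perfectly periodic breathing.
    tap_jitter_sd
        Standard deviation of the observer's motor timing error, seconds.
    p_missed
        Probability that a breath is not tapped (merges two intervals).
    p_extra
        Probability, per inter-tap gap, of a spurious extra tap at a uniform
        position inside the gap (splits an interval).
    duration
        Tapping session length in seconds, measured from the first tap.
    seed
        Seed for the private random generator; identical models yield
        identical tap logs.
    """

    rr_true: float
    breath_cv: float = 0.10
    tap_jitter_sd: float = 0.05
    p_missed: float = 0.05
    p_extra: float = 0.02
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rr_true > 0:
            raise ValueError(f"rr_true must be positive, got {self.rr_true}")
        if self.breath_cv < 0:
            raise ValueError("breath_cv must be >= 0")
        if self.tap_jitter_sd < 0:
            raise ValueError("tap_jitter_sd must be >= 0")
        for name in ("p_missed", "p_extra"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """A simulated study: ``n_subjects`` observers, each tapping every video.

    Per-subject tapping skill varies through a lognormal multiplier
    (``sigma = subject_jitter_sigma``) on ``tap_jitter_sd``.  Video order is
    randomized per subject; the returned logs are in presentation order.

    ``breath_cv`` may be a single value applied to every video, or ``None``
    (the default) to use per-video values from ``video_breath_cvs``.
    """

    video_rrs: tuple[float, ...] = TABLE_RRS
    video_breath_cvs: tuple[float, ...] = TABLE_BREATH_CVS
    n_subjects: int = 30
    breath_cv: Optional[float] = None
    tap_jitter_sd: float = 0.05
    p_missed: float = 0.05
    p_extra: float = 0.02
    duration: float = 60.0
    subject_jitter_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(rr <= 0 for rr in self.video_rrs):
            raise ValueError("all video RRs must be positive")
        if self.breath_cv is None and len(self.video_breath_cvs) != len(self.video_rrs):
            raise ValueError("video_breath_cvs must match video_rrs in length")

    def breath_cv_for(self, video_index: int) -> float:
        return self.breath_cv if self.breath_cv is not None else self.video_breath_cvs[video_index]


def _breath_onsets(rng: np.random.Generator, mu: float, cv: float, duration: float) -> np.ndarray:
    """Gamma-renewal breath onset times on [0, duration], starting at 0."""
    n_block = max(8, int(duration / mu * 1.5) + 8)
    times = [0.0]
    t = 0.0
    while t <= duration:
        if cv == 0.0:
            ivs = np.full(n_block, mu)
        else:
            shape = 1.0 / cv**2
            ivs = rng.gamma(shape, mu * cv**2, n_block)
        for iv in ivs:
            t += iv
            if t > duration + 1e-9:
                break
            times.append(t)
    return np.asarray(times)


def simulate_taps(
    model: TapperModel,
    subject_id: str = "sim",
    video_id: Optional[str] = None,
    rr_ref: Optional[float] = None,
) -> TapLog:
    """Generate one tap log from a :class:`TapperModel`.

    In the noise-free limit (all noise parameters zero) taps are exactly
    ``60 / rr_true`` seconds apart.  Times are shifted so the first tap is at
    0.0 and truncated ``duration`` seconds after it.
    """
    rng = np.random.default_rng(model.seed)
    mu = 60.0 / model.rr_true
    taps = _breath_onsets(rng, mu, model.breath_cv, model.duration)

    if model.p_missed > 0 and taps.size:
        keep = rng.random(taps.size) >= model.p_missed
        taps = taps[keep]

    if model.tap_jitter_sd > 0 and taps.size > 1:
        jit = rng.normal(0.0, model.tap_jitter_sd, taps.size)
        for _ in range(1000):
            jittered = taps + jit
            bad = np.flatnonzero(np.diff(jittered) <= 0)
            if bad.size == 0:
                break
            redo = np.unique(np.concatenate([bad, bad + 1]))
            jit[redo] = rng.normal(0.0, model.tap_jitter_sd, redo.size)
        else:
            raise RuntimeError("could not jitter taps into strictly increasing order")
        taps = taps + jit

    if model.p_extra > 0 and taps.size > 1:
        gaps = np.flatnonzero(rng.random(taps.size - 1) < model.p_extra)
        if gaps.size:
            extras = rng.uniform(taps[gaps], taps[gaps + 1])
            taps = np.sort(np.concatenate([taps, extras]))
            # a tie with an existing tap has probability zero; drop if it occurs
            taps = taps[np.concatenate([[True], np.diff(taps) > 0])]

    if taps.size:
        taps = taps - taps[0]
        taps = taps[taps <= model.duration + 1e-9]

    return TapLog(
        subject_id=subject_id,
        video_id=video_id if video_id is not None else f"rr{model.rr_true:g}",
        tap_times=tuple(taps.tolist()),
        rr_ref=float(rr_ref) if rr_ref is not None else model.rr_true,
    )


def simulate_study(design: StudyDesign) -> list[TapLog]:
    """Generate one tap log per (subject, video).

    A single seed streams to per-subject substreams (``SeedSequence.spawn``),
    so any subset of subjects reproduces independently of the others.  Logs
    are returned in each subject's randomized presentation order.
    """
    root = np.random.SeedSequence(design.seed)
    logs: list[TapLog] = []
    n_videos = len(design.video_rrs)
    for s_idx, sseq in enumerate(root.spawn(design.n_subjects)):
        srng = np.random.default_rng(sseq)
        jitter_s = design.tap_jitter_sd * srng.lognormal(
            -0.5 * design.subject_jitter_sigma**2, design.subject_jitter_sigma
        )
        order = srng.permutation(n_videos)
        log_seeds = srng.integers(0, 2**31 - 1, size=n_videos)
        for v_idx in order:
            rr = design.video_rrs[v_idx]
            model = TapperModel(
                rr_true=rr,
                breath_cv=design.breath_cv_for(v_idx),
                tap_jitter_sd=jitter_s,
                p_missed=design.p_missed,
                p_extra=design.p_extra,
                duration=design.duration,
                seed=int(log_seeds[v_idx]),
            )
            logs.append(
                simulate_taps(
                    model,
                    subject_id=f"S{s_idx:02d}",
                    video_id=f"V{v_idx:02d}",
                    rr_ref=rr,
                )
            )
    return logs
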