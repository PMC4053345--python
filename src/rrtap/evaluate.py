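"""Accuracy, efficiency and agreement metrics, and the (z, Th_C) sensitivity grid.

Accuracy is the normalized root mean square error (NRMSE) of estimated vs
reference rate, in percent, with per-observation normalization:

    NRMSE = 100 * sqrt( (1/n) * sum_i ((RR_i - RRref_i) / RRref_i)^2 )

Efficiency E is the time from the first tap to the report; observations that
do not complete within the 60 s cap contribute E = 60 s to every efficiency
statistic and reduce the completion rate CR.  NRMSE is computed over completed
observations only — failures are penalized solely through E and CR.

The grid replay enumerates, for every tap log and every set size z, the
consistency of all sliding windows of z intervals once, then resolves the
earliest accepted window for each threshold.  This is an exhaustive
window-by-window search, algebraically equivalent to (and cross-checked in the
test suite against) the streaming estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import RREstimate, TapLog

__all__ = [
    "EvaluationSummary",
    "BlandAltman",
    "ReplayMatrix",
    "nrmse",
    "efficiency_stats",
    "bland_altman",
    "replay_matrix",
    "replay_grid",
    "all_taps_reference",
    "regression_summary",
    "DEFAULT_Z_VALUES",
    "DEFAULT_TH_C_VALUES",
]

DEFAULT_Z_VALUES: tuple[int, ...] = tuple(range(2, 16))
DEFAULT_TH_C_VALUES: tuple[float, ...] = tuple(float(t) for t in range(2, 31))


@dataclass(frozen=True)
class EvaluationSummary:
    """Accuracy/efficiency/completion summary for one (z, th_c) configuration.

    ``nrmse`` is ``None`` when no observation completed.  ``th_c`` is ``None``
    for the threshold-disabled configuration.
    """

    z: int
    th_c: Optional[float]
    n: int
    n_fail: int
    nrmse: Optional[float]
    e_median: float
    e_mean: float
    e_p95: float
    cr: float


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between estimated and reference RR: bias and ±2 SD limits."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def nrmse(pairs: Sequence[tuple[float, float]]) -> float:
    """NRMSE in percent of (estimate, reference) pairs."""
    if len(pairs) == 0:
        raise ValueError("nrmse needs at least one (RR, RR_ref) pair")
    sq = 0.0
    for rr, ref in pairs:
        if not ref > 0:
            raise ValueError(f"reference RR must be positive, got {ref}")
        sq += ((rr - ref) / ref) ** 2
    return 100.0 * math.sqrt(sq / len(pairs))


def _e_values(estimates: Sequence[RREstimate], max_duration: float) -> np.ndarray:
    return np.array(
        [e.efficiency if e.completed else max_duration for e in estimates], dtype=float
    )


def efficiency_stats(
    estimates: Sequence[RREstimate], max_duration: float = 60.0
) -> dict[str, float]:
    """Efficiency statistics and completion rate over a set of estimates.

    Non-completed observations contribute ``E = max_duration`` to the median,
    mean and 95th percentile (linear interpolation) and decrement CR.
    """
    if len(estimates) == 0:
        raise ValueError("efficiency_stats needs at least one estimate")
    e = _e_values(estimates, max_duration)
    n_fail = sum(not est.completed for est in estimates)
    return {
        "e_median": float(np.median(e)),
        "e_mean": float(np.mean(e)),
        "e_p95": float(np.percentile(e, 95)),
        "cr": 100.0 * (len(estimates) - n_fail) / len(estimates),
        "n": len(estimates),
        "n_fail": n_fail,
    }


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltman:
    """Bland–Altman agreement: bias (mean difference), SD, and bias ± 2·SD."""
    if len(pairs) < 2:
        raise ValueError("bland_altman needs at least two pairs")
    diffs = np.array([rr - ref for rr, ref in pairs], dtype=float)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias, sd, bias - 2.0 * sd, bias + 2.0 * sd, len(pairs))


def _window_profile(
    log: TapLog, z: int, max_duration: float
) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(C, RR, accept-time) for every window of z intervals within the cap."""
    t = np.asarray(log.tap_times, dtype=float)
    if t.size:
        t = t[t - t[0] <= max_duration + 1e-12]
    if t.size < z + 1:
        return None
    iv = np.diff(t)
    w = sliding_window_view(iv, z)
    med = np.median(w, axis=1)
    c = 100.0 * np.abs(w - med[:, None]).max(axis=1) / med
    return c, 60.0 / med, t[z:] - t[0]


@dataclass(frozen=True)
class ReplayMatrix:
    """Per-log replay results over a (z, th_c) grid.

    Arrays are indexed ``[log, z, th]``; the last threshold index corresponds
    to the disabled threshold when ``th_c_values`` ends with ``None``.
    ``e`` already holds ``max_duration`` for non-completed cells.
    """

    completed: np.ndarray
    rr: np.ndarray
    e: np.ndarray
    rr_ref: np.ndarray
    z_values: tuple[int, ...]
    th_c_values: tuple[Optional[float], ...]
    max_duration: float

    def _indices(self, z: int, th_c: Optional[float]) -> tuple[int, int]:
        return self.z_values.index(z), self.th_c_values.index(th_c)

    def summary(
        self,
        z: int,
        th_c: Optional[float],
        mask: Optional[np.ndarray] = None,
    ) -> EvaluationSummary:
        """Aggregate one grid cell over all logs, or the masked subset."""
        zi, ti = self._indices(z, th_c)
        sel = slice(None) if mask is None else mask
        comp = self.completed[sel, zi, ti]
        rr = self.rr[sel, zi, ti]
        e = self.e[sel, zi, ti]
        ref = self.rr_ref[sel]
        n = int(comp.size)
        n_fail = int(n - comp.sum())
        if n_fail < n:
            rel = (rr[comp] - ref[comp]) / ref[comp]
            nr: Optional[float] = 100.0 * float(np.sqrt(np.mean(rel**2)))
        else:
            nr = None
        return EvaluationSummary(
            z=z,
            th_c=th_c,
            n=n,
            n_fail=n_fail,
            nrmse=nr,
            e_median=float(np.median(e)),
            e_mean=float(np.mean(e)),
            e_p95=float(np.percentile(e, 95)),
            cr=100.0 * (n - n_fail) / n,
        )

    def to_frame(self, mask: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Tidy grid: one row per (z, th_c) cell; th_c is NaN when disabled."""
        rows = []
        for z in self.z_values:
            for th in self.th_c_values:
                s = self.summary(z, th, mask)
                rows.append(
                    {
                        "z": s.z,
                        "th_c": np.nan if s.th_c is None else s.th_c,
                        "nrmse": np.nan if s.nrmse is None else s.nrmse,
                        "n": s.n,
                        "n_fail": s.n_fail,
                        "cr": s.cr,
                        "e_median": s.e_median,
                        "e_mean": s.e_mean,
                        "e_p95": s.e_p95,
                    }
                )
        return pd.DataFrame(rows)


def replay_matrix(
    logs: Sequence[TapLog],
    z_values: Iterable[int] = DEFAULT_Z_VALUES,
    th_c_values: Iterable[float] = DEFAULT_TH_C_VALUES,
    *,
    include_disabled: bool = True,
    rr_min: float = 2.0,
    rr_max: float = 140.0,
    max_duration: float = 60.0,
) -> ReplayMatrix:
    """Replay every log offline over the full grid of configurations.

    For each log and z, all sliding windows are enumerated once; each
    threshold then resolves to the earliest window that passes both the
    consistency test and the reportable-rate range.
    """
    if len(logs) == 0:
        raise ValueError("replay needs at least one tap log")
    zs = tuple(int(z) for z in z_values)
    ths_num = tuple(float(t) for t in th_c_values)
    ths: tuple[Optional[float], ...] = ths_num + ((None,) if include_disabled else ())
    th_arr = np.asarray(ths_num, dtype=float)
    nl, nz, nt = len(logs), len(zs), len(ths)
    completed = np.zeros((nl, nz, nt), dtype=bool)
    rr = np.full((nl, nz, nt), np.nan)
    e = np.full((nl, nz, nt), float(max_duration))
    for li, log in enumerate(logs):
        for zi, z in enumerate(zs):
            prof = _window_profile(log, z, max_duration)
            if prof is None:
                continue
            c, rr_w, at = prof
            in_range = (rr_w >= rr_min) & (rr_w <= rr_max)
            if ths_num:
                ok = in_range[None, :] & (c[None, :] <= th_arr[:, None])
                first = ok.argmax(axis=1)
                hit = ok.any(axis=1)
                completed[li, zi, : len(ths_num)] = hit
                rr[li, zi, : len(ths_num)][hit] = rr_w[first[hit]]
                e[li, zi, : len(ths_num)][hit] = at[first[hit]]
            if include_disabled and in_range.any():
                j = int(in_range.argmax())
                completed[li, zi, -1] = True
                rr[li, zi, -1] = rr_w[j]
                e[li, zi, -1] = at[j]
    return ReplayMatrix(
        completed=completed,
        rr=rr,
        e=e,
        rr_ref=np.array([log.rr_ref for log in logs], dtype=float),
        z_values=zs,
        th_c_values=ths,
        max_duration=float(max_duration),
    )


def replay_grid(
    logs: Sequence[TapLog],
    z_values: Iterable[int] = DEFAULT_Z_VALUES,
    th_c_values: Iterable[float] = DEFAULT_TH_C_VALUES,
    *,
    include_disabled: bool = True,
    rr_min: float = 2.0,
    rr_max: float = 140.0,
    max_duration: float = 60.0,
) -> pd.DataFrame:
    """Sensitivity grid: one :class:`EvaluationSummary` row per (z, th_c)."""
    return replay_matrix(
        logs,
        z_values,
        th_c_values,
        include_disabled=include_disabled,
        rr_min=rr_min,
        rr_max=rr_max,
        max_duration=max_duration,
    ).to_frame()


def all_taps_reference(
    logs: Sequence[TapLog], max_duration: float = 60.0
) -> dict[str, float]:
    """Reference estimator using all taps within the cap: 60 / median of all
    intervals.  Its NRMSE is the asymptote the grid approaches at large z."""
    pairs = []
    n_skipped = 0
    for log in logs:
        t = np.asarray(log.tap_times, dtype=float)
        if t.size:
            t = t[t - t[0] <= max_duration + 1e-12]
        if t.size < 2:
            n_skipped += 1
            continue
        pairs.append((60.0 / float(np.median(np.diff(t))), log.rr_ref))
    if not pairs:
        raise ValueError("no log had at least two taps within the cap")
    return {"nrmse": nrmse(pairs), "n": len(pairs), "n_skipped": n_skipped}


def regression_summary(grid: pd.DataFrame) -> dict[str, dict]:
    """Descriptive OLS fits of nrmse and e_median on (z, th_c) over the grid.

    Threshold-disabled rows and cells with undefined NRMSE are dropped.
    Returns, per response, the coefficient table, p-values and R².
    """
    import statsmodels.formula.api as smf

    sub = grid.dropna(subset=["th_c"])
    if sub["z"].nunique() < 2 or sub["th_c"].nunique() < 2:
        raise ValueError("regression needs at least 2 distinct z and th_c levels")
    out: dict[str, dict] = {}
    for response in ("nrmse", "e_median"):
        data = sub.dropna(subset=[response])
        fit = smf.ols(f"{response} ~ z + th_c", data=data).fit()
        out[response] = {
            "coef": dict(fit.params),
            "pvalues": dict(fit.pvalues),
            "r_squared": float(fit.rsquared),
            "n_cells": int(fit.nobs),
        }
    return out
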