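"""Cost-function optimization of (z, Th_C) with k-fold cross-validation.

The trade-off between accuracy and speed is scored by

    J(z, Th_C) = w * NRMSE + E_median + E_95

with the weighting factor ``w`` chosen so that the upper acceptable limits for
time (15 s) and error (4%) contribute equally: ``w = 15 / 4 = 3.75`` seconds
per percent.  The completion rate enters only through the E = 60 s penalty
that failed measurements already carry inside the efficiency statistics.

Cross-validation assigns, per video, ``per_bin`` observations to each of
``n_folds`` bins; each bin serves once as the test set, the minimizing
(z, Th_C) on the training bins is recorded, and the modal minimizer across
folds is selected.  Its per-fold test performance is compared against the
threshold-free estimator at the same set size with a paired two-sided t-test.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import TapLog
from .evaluate import (
    DEFAULT_TH_C_VALUES,
    DEFAULT_Z_VALUES,
    EvaluationSummary,
    ReplayMatrix,
    replay_matrix,
)

__all__ = [
    "CostConfig",
    "PairedComparison",
    "OptimizationResult",
    "cost",
    "paired_comparison",
    "crossvalidate",
]


@dataclass(frozen=True)
class CostConfig:
    """Acceptability limits and the derived accuracy weight.

    ``weight_w`` defaults to ``e_limit / nrmse_limit`` (3.75 s per percent
    NRMSE) so the two limits carry equal weight in the cost.
    """

    e_limit: float = 15.0
    nrmse_limit: float = 4.0
    weight_w: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.e_limit > 0 and self.nrmse_limit > 0):
            raise ValueError("e_limit and nrmse_limit must be positive")
        if self.weight_w is None:
            object.__setattr__(self, "weight_w", self.e_limit / self.nrmse_limit)
        elif not self.weight_w > 0:
            raise ValueError("weight_w must be positive")


def cost(summary: EvaluationSummary, config: CostConfig = CostConfig()) -> float:
    """J = w·NRMSE + E_median + E_95; infinite when no observation completed."""
    if summary.nrmse is None:
        return math.inf
    return config.weight_w * summary.nrmse + summary.e_median + summary.e_p95


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test on per-fold values.

    When the fold-wise differences have zero variance the t statistic is
    undefined; ``degenerate`` is set and the verdict follows the sign of the
    (constant) difference: no difference → not significant, constant nonzero
    shift → significant at any level.
    """

    n: int
    mean_diff: float
    t: Optional[float]
    p: Optional[float]
    significant: bool
    degenerate: bool
    alpha: float = 0.05


def paired_comparison(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> PairedComparison:
    """Paired two-sided t-test of ``a`` vs ``b`` (paired by fold)."""
    if len(a) != len(b):
        raise ValueError("paired sequences must have equal length")
    if len(a) < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    mean_diff = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            return PairedComparison(len(d), 0.0, 0.0, 1.0, False, True, alpha)
        return PairedComparison(len(d), mean_diff, None, None, True, True, alpha)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(len(d), mean_diff, float(t), float(p), bool(p < alpha), False, alpha)


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the cross-validated cost optimization."""

    per_fold_best: tuple[tuple[int, float], ...]
    selected: tuple[int, float]
    test_selected: tuple[EvaluationSummary, ...]
    test_baseline: tuple[EvaluationSummary, ...]
    comparison: Optional[PairedComparison]
    baseline: tuple[int, Optional[float]]
    fold_costs: np.ndarray  # (n_folds, n_z, n_th) training costs
    bins: tuple[tuple[int, ...], ...]  # log indices per bin
    seed: int

    def to_dict(self) -> dict:
        """JSON-serializable summary (per-fold table + selected parameters)."""
        def _summ(s: EvaluationSummary) -> dict:
            return {
                "z": s.z,
                "th_c": s.th_c,
                "n": s.n,
                "n_fail": s.n_fail,
                "nrmse": s.nrmse,
                "e_median": s.e_median,
                "e_mean": s.e_mean,
                "e_p95": s.e_p95,
                "cr": s.cr,
            }

        comp = None
        if self.comparison is not None:
            comp = {
                "n": self.comparison.n,
                "mean_diff": self.comparison.mean_diff,
                "t": self.comparison.t,
                "p": self.comparison.p,
                "significant": self.comparison.significant,
                "degenerate": self.comparison.degenerate,
                "alpha": self.comparison.alpha,
            }
        return {
            "selected": {"z": self.selected[0], "th_c": self.selected[1]},
            "baseline": {"z": self.baseline[0], "th_c": self.baseline[1]},
            "per_fold_best": [{"z": z, "th_c": t} for z, t in self.per_fold_best],
            "test_selected": [_summ(s) for s in self.test_selected],
            "test_baseline": [_summ(s) for s in self.test_baseline],
            "comparison": comp,
            "seed": self.seed,
        }


def _assign_bins(
    logs: Sequence[TapLog], n_folds: int, per_bin: int, rng: np.random.Generator
) -> list[list[int]]:
    """Per video, assign ``per_bin`` random observations to each bin."""
    by_video: dict[str, list[int]] = defaultdict(list)
    for i, log in enumerate(logs):
        by_video[log.video_id].append(i)
    bins: list[list[int]] = [[] for _ in range(n_folds)]
    for vid in sorted(by_video):
        idx = by_video[vid]
        if len(idx) != n_folds * per_bin:
            raise ValueError(
                f"video {vid} has {len(idx)} observations; "
                f"{n_folds} folds x {per_bin} per bin need exactly {n_folds * per_bin}"
            )
        perm = rng.permutation(len(idx))
        for b in range(n_folds):
            for k in range(per_bin):
                bins[b].append(idx[perm[b * per_bin + k]])
    return bins


def _fold_cost_grid(
    matrix: ReplayMatrix, train_mask: np.ndarray, cfg: CostConfig, n_enabled: int
) -> np.ndarray:
    """Vectorized training cost for every enabled (z, th_c) cell."""
    comp = matrix.completed[train_mask][:, :, :n_enabled]
    rr = matrix.rr[train_mask][:, :, :n_enabled]
    e = matrix.e[train_mask][:, :, :n_enabled]
    ref = matrix.rr_ref[train_mask][:, None, None]
    relsq = np.where(comp, ((rr - ref) / ref) ** 2, 0.0)
    n_comp = comp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nr = 100.0 * np.sqrt(relsq.sum(axis=0) / n_comp)
    j = cfg.weight_w * nr + np.median(e, axis=0) + np.percentile(e, 95, axis=0)
    j[n_comp == 0] = np.inf
    return j


def crossvalidate(
    logs: Sequence[TapLog],
    *,
    z_values: Iterable[int] = DEFAULT_Z_VALUES,
    th_c_values: Iterable[float] = DEFAULT_TH_C_VALUES,
    cost_config: CostConfig = CostConfig(),
    baseline: tuple[int, Optional[float]] = (4, None),
    n_folds: int = 15,
    per_bin: int = 2,
    rr_min: float = 2.0,
    rr_max: float = 140.0,
    max_duration: float = 60.0,
    seed: int = 0,
) -> OptimizationResult:
    """Select (z, Th_C) by k-fold cross-validated cost minimization.

    Per fold, the cost is minimized over the enabled-threshold grid on the
    training bins (ties resolved toward lower z, then lower Th_C); the modal
    minimizer across folds is selected (ties: lower mean training cost, then
    lower z, then lower Th_C).  Test-set summaries are computed per fold for
    the selection and for the ``baseline`` configuration, and their per-fold
    NRMSE values compared with a paired two-sided t-test.
    """
    rng = np.random.default_rng(seed)
    matrix = replay_matrix(
        logs,
        z_values,
        th_c_values,
        include_disabled=True,
        rr_min=rr_min,
        rr_max=rr_max,
        max_duration=max_duration,
    )
    zs = matrix.z_values
    enabled = [t for t in matrix.th_c_values if t is not None]
    n_enabled = len(enabled)
    bins = _assign_bins(logs, n_folds, per_bin, rng)

    n_logs = len(logs)
    per_fold_best: list[tuple[int, float]] = []
    fold_costs = np.empty((n_folds, len(zs), n_enabled))
    for b in range(n_folds):
        train = np.ones(n_logs, dtype=bool)
        train[bins[b]] = False
        j = _fold_cost_grid(matrix, train, cost_config, n_enabled)
        fold_costs[b] = j
        zi, ti = np.unravel_index(np.argmin(j), j.shape)  # first min: low z, low th
        per_fold_best.append((zs[zi], enabled[ti]))

    counts = Counter(per_fold_best)
    top = max(counts.values())
    candidates = [cell for cell, c in counts.items() if c == top]
    if len(candidates) > 1:
        mean_cost = {
            cell: fold_costs[:, zs.index(cell[0]), enabled.index(cell[1])].mean()
            for cell in candidates
        }
        candidates.sort(key=lambda cell: (mean_cost[cell], cell[0], cell[1]))
    selected = candidates[0]

    test_selected = []
    test_baseline = []
    for b in range(n_folds):
        mask = np.zeros(n_logs, dtype=bool)
        mask[bins[b]] = True
        test_selected.append(matrix.summary(selected[0], selected[1], mask))
        test_baseline.append(matrix.summary(baseline[0], baseline[1], mask))

    pairs = [
        (s.nrmse, t.nrmse)
        for s, t in zip(test_selected, test_baseline)
        if s.nrmse is not None and t.nrmse is not None
    ]
    comparison = None
    if len(pairs) >= 2:
        comparison = paired_comparison([p[0] for p in pairs], [p[1] for p in pairs])

    return OptimizationResult(
        per_fold_best=tuple(per_fold_best),
        selected=selected,
        test_selected=tuple(test_selected),
        test_baseline=tuple(test_baseline),
        comparison=comparison,
        baseline=baseline,
        fold_costs=fold_costs,
        bins=tuple(tuple(b) for b in bins),
        seed=seed,
    )
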