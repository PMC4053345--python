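"""Tests for accuracy/efficiency metrics, Bland-Altman, the sensitivity grid
and the descriptive regression summary."""

import numpy as np
import pandas as pd
import pytest

from rrtap import (
    EstimatorConfig,
    RREstimate,
    StudyDesign,
    TapLog,
    all_taps_reference,
    bland_altman,
    efficiency_stats,
    estimate_streaming,
    nrmse,
    regression_summary,
    replay_grid,
    replay_matrix,
    simulate_study,
    simulate_taps,
    TapperModel,
)


def _est(e, completed=True, rr=40.0):
    return RREstimate(rr if completed else None, e, 5, None, completed)


class TestNrmse:
    def test_perfect_estimate(self):
        assert nrmse([(40.0, 40.0)]) == 0.0

    def test_single_relative_error(self):
        assert nrmse([(42.0, 40.0)]) == pytest.approx(5.0, abs=1e-9)

    def test_percent_scale_maps_to_absolute_error(self):
        # 5.6% NRMSE at a reference of 40 corresponds to 2.24 breaths/min RMS
        pairs = [(40.0 + 2.24, 40.0), (40.0 - 2.24, 40.0)]
        assert nrmse(pairs) == pytest.approx(5.6, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            nrmse([])


class TestEfficiencyStats:
    def test_all_completed(self):
        s = efficiency_stats([_est(6.0), _est(8.0), _est(10.0)])
        assert s["e_median"] == 8.0 and s["e_mean"] == 8.0 and s["cr"] == 100.0

    def test_failure_contributes_cap(self):
        s = efficiency_stats([_est(6.0), _est(8.0), _est(60.0, completed=False)])
        assert s["e_mean"] == pytest.approx(np.mean([6.0, 8.0, 60.0]))
        assert s["cr"] == pytest.approx(200.0 / 3.0)
        assert s["n_fail"] == 1

    def test_all_failed(self):
        s = efficiency_stats([_est(60.0, completed=False)] * 5)
        assert s["cr"] == 0.0 and s["e_mean"] == 60.0

    def test_no_failures_reduces_to_ordinary_percentiles(self):
        e = [3.0, 5.0, 7.0, 9.0, 11.0]
        s = efficiency_stats([_est(v) for v in e])
        assert s["e_median"] == np.median(e)
        assert s["e_p95"] == pytest.approx(np.percentile(e, 95))


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([(40.0, 40.0)] * 3)
        assert ba.bias == 0.0 and ba.sd == 0.0

    def test_two_point_hand_computation(self):
        ba = bland_altman([(41.0, 40.0), (39.0, 40.0)])
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.sd == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_limits_of_agreement(self):
        ba = bland_altman([(42.0, 40.0), (42.0, 40.0), (38.0, 40.0), (38.0, 40.0)])
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_high == pytest.approx(2.0 * np.sqrt(16.0 / 3.0), abs=1e-3)
        assert ba.loa_low == pytest.approx(-ba.loa_high, abs=1e-12)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(40.0, 40.0)])


def _noise_free_logs(rr=40.0, n=5):
    return [
        simulate_taps(
            TapperModel(rr_true=rr, breath_cv=0.0, tap_jitter_sd=0.0,
                        p_missed=0.0, p_extra=0.0, seed=i),
            subject_id=f"S{i}",
        )
        for i in range(n)
    ]


class TestReplayGrid:
    def test_noise_free_grid_is_exact_everywhere(self):
        grid = replay_grid(_noise_free_logs())
        assert (grid["cr"] == 100.0).all()
        assert np.allclose(grid["nrmse"], 0.0, atol=1e-9)

    def test_grid_shape(self):
        grid = replay_grid(_noise_free_logs(n=2))
        assert len(grid) == 14 * 29 + 14  # full grid plus the disabled column

    def test_matches_streaming_estimator_cell_by_cell(self):
        logs = simulate_study(StudyDesign(n_subjects=2, seed=21))
        m = replay_matrix(logs, z_values=[2, 4, 9], th_c_values=[4.0, 13.0])
        for zi, z in enumerate(m.z_values):
            for ti, th in enumerate(m.th_c_values):
                for li, log in enumerate(logs):
                    est = estimate_streaming(log, EstimatorConfig(z=z, th_c=th))
                    assert m.completed[li, zi, ti] == est.completed
                    assert m.e[li, zi, ti] == pytest.approx(est.efficiency, rel=1e-12)
                    if est.completed:
                        assert m.rr[li, zi, ti] == pytest.approx(est.rr, rel=1e-12)

    def test_e_mean_non_increasing_in_threshold(self):
        logs = simulate_study(StudyDesign(n_subjects=3, seed=13))
        grid = replay_grid(logs).dropna(subset=["th_c"])
        for z, sub in grid.groupby("z"):
            e = sub.sort_values("th_c")["e_mean"].to_numpy()
            assert (np.diff(e) <= 1e-9).all()

    def test_cr_non_decreasing_in_threshold_exactly(self):
        logs = simulate_study(StudyDesign(n_subjects=3, seed=17))
        grid = replay_grid(logs).dropna(subset=["th_c"])
        for z, sub in grid.groupby("z"):
            cr = sub.sort_values("th_c")["cr"].to_numpy()
            assert (np.diff(cr) >= -1e-9).all()

    def test_cr_trends_down_with_set_size(self):
        # Not exact per log set: the even/odd median parity can let a larger
        # window pass where smaller ones fail.  The trend over a study holds.
        logs = simulate_study(StudyDesign(n_subjects=30, seed=17))
        m = replay_matrix(logs, th_c_values=[10.0])
        cr = {z: m.summary(z, 10.0).cr for z in (2, 8, 15)}
        assert cr[15] < cr[8] < cr[2]

    def test_impossible_cell_flags_undefined_nrmse(self):
        # two wildly inconsistent logs: tight threshold at large z never accepts
        logs = [
            TapLog("a", "v", (0.0, 1.0, 5.0, 6.0, 11.0, 12.0, 18.0, 19.0), 40.0),
            TapLog("b", "v", (0.0, 2.0, 3.0, 9.0, 10.0, 17.0, 18.0, 26.0), 40.0),
        ]
        grid = replay_grid(logs, z_values=[6], th_c_values=[2.0])
        row = grid[(grid.z == 6) & (grid.th_c == 2.0)].iloc[0]
        assert row["cr"] == 0.0 and np.isnan(row["nrmse"]) and row["e_mean"] == 60.0

    def test_all_taps_reference_on_noise_free_logs(self):
        ref = all_taps_reference(_noise_free_logs())
        assert ref["nrmse"] == pytest.approx(0.0, abs=1e-9)
        assert ref["n"] == 5


class TestRegressionSummary:
    @staticmethod
    def _grid_from_surface(fn):
        rows = []
        for z in range(2, 8):
            for th in range(2, 12):
                rows.append(
                    {"z": z, "th_c": float(th), "nrmse": fn(z, th), "n": 10,
                     "n_fail": 0, "cr": 100.0, "e_median": fn(z, th),
                     "e_mean": 1.0, "e_p95": 1.0}
                )
        return pd.DataFrame(rows)

    def test_exact_linear_surface(self):
        rep = regression_summary(self._grid_from_surface(lambda z, th: 10.0 - z))
        assert rep["nrmse"]["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert rep["nrmse"]["coef"]["z"] == pytest.approx(-1.0, abs=1e-9)

    def test_constant_surface_has_zero_slopes(self):
        rep = regression_summary(self._grid_from_surface(lambda z, th: 5.0))
        assert rep["nrmse"]["coef"]["z"] == pytest.approx(0.0, abs=1e-9)
        assert rep["nrmse"]["coef"]["th_c"] == pytest.approx(0.0, abs=1e-9)

    def test_threshold_speeds_up_measurement_on_synthetic_grid(self):
        logs = simulate_study(StudyDesign(n_subjects=10, seed=31))
        rep = regression_summary(replay_grid(logs))
        assert rep["e_median"]["coef"]["th_c"] < 0  # looser threshold -> faster

    def test_degenerate_design_raises(self):
        grid = self._grid_from_surface(lambda z, th: 1.0)
        with pytest.raises(ValueError):
            regression_summary(grid[grid.z == 2])
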