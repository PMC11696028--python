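"""Synthetic eye/hand traces and the Poisson population generator."""

import numpy as np
import pytest

from mentalpong.task import (FrameGeometry, TaskCondition, analyze_condition,
                             paddle_update, simulate_trajectory)
from mentalpong.synth import (BehaviorTraces, gen_eye_trace, gen_paddle_trace,
                              gen_population_spikes, generate_dataset,
                              make_grid, make_ground_truth,
                              tracking_error_curves)


@pytest.fixture(scope="module")
def straight_cond():
    return analyze_condition(TaskCondition(x0=-8, y0=4, dx0=8, dy0=-6),
                             FrameGeometry())


@pytest.fixture(scope="module")
def straight_traj(straight_cond):
    return simulate_trajectory(straight_cond)


class TestEyeTrace:
    def test_noiseless_zero_lag_eye_equals_ball(self, straight_traj):
        eye = gen_eye_trace(straight_traj, lag_ms=0, noise_sd=0,
                            saccade_rate_hz=0)
        bx = np.interp(eye.eye_times, straight_traj.times,
                       straight_traj.ball_x)
        by = np.interp(eye.eye_times, straight_traj.times,
                       straight_traj.ball_y)
        assert np.allclose(eye.eye_x, bx, atol=1e-9)
        assert np.allclose(eye.eye_y, by, atol=1e-9)

    def test_pure_lag_error_matches_shift_oracle(self, straight_traj):
        lag = 200.0
        eye = gen_eye_trace(straight_traj, lag_ms=lag, noise_sd=0,
                            saccade_rate_hz=0)
        t = eye.eye_times
        ball_now = np.interp(t, straight_traj.times, straight_traj.ball_x)
        ball_lag = np.interp(np.maximum(t - lag, 0), straight_traj.times,
                             straight_traj.ball_x)
        err = np.abs(eye.eye_x - ball_now)
        assert np.allclose(err, np.abs(ball_lag - ball_now), atol=1e-9)

    def test_lag_beyond_trial_rejected(self, straight_traj):
        with pytest.raises(ValueError, match="exceeds trial duration"):
            gen_eye_trace(straight_traj, lag_ms=1e6)

    def test_seed_reproducibility(self, straight_traj):
        a = gen_eye_trace(straight_traj, seed=7)
        b = gen_eye_trace(straight_traj, seed=7)
        assert np.array_equal(a.eye_x, b.eye_x)


class TestPaddleTrace:
    def test_delay_beyond_trial_leaves_paddle_at_center(self, straight_cond):
        tr = gen_paddle_trace(straight_cond, movement_delay_ms=1e5)
        assert np.allclose(tr.paddle_y, 0.0)
        assert not tr.triggered.any()

    def test_final_error_matches_speed_limit_closed_form(self):
        # |yf| - 0.01 deg/ms * (T - delay), floored at ~0
        cond = analyze_condition(TaskCondition(x0=-8, y0=0, dx0=8, dy0=8.5),
                                 FrameGeometry())
        for delay in (0.0, 1000.0, 1800.0):
            tr = gen_paddle_trace(cond, movement_delay_ms=delay)
            final = paddle_update(tr.joystick_voltage[-1], tr.paddle_y[-1])
            expect = max(0.0, abs(cond.yf) - 0.01 * (cond.duration_ms - delay))
            # bang-bang quantizes motion to refresh steps -> one-step slack
            assert abs(cond.yf - final) == pytest.approx(expect, abs=0.17)

    def test_per_refresh_displacement_bounded(self, straight_cond):
        tr = gen_paddle_trace(straight_cond, movement_delay_ms=300.0)
        assert np.max(np.abs(np.diff(tr.paddle_y))) <= 0.17 + 1e-9

    def test_voltage_trace_replays_through_paddle_update(self, straight_cond):
        tr = gen_paddle_trace(straight_cond, movement_delay_ms=500.0)
        y = 0.0
        replay = []
        for v in tr.joystick_voltage:
            replay.append(y)
            y = paddle_update(v, y)
        assert np.allclose(replay, tr.paddle_y, atol=1e-12)


class TestPopulationSpikes:
    def test_counts_are_nonnegative_integers(self, small_dataset):
        _, _, _, spikes = small_dataset
        vals = spikes.counts[np.isfinite(spikes.counts)]
        assert (vals >= 0).all()
        assert np.allclose(vals, np.round(vals))

    def test_zero_gain_mean_rate_matches_baseline(self, conditions20, grid20):
        gt = make_ground_truth(conditions20, grid20, n_units=30, gain=0.0,
                               seed=2)
        spikes = gen_population_spikes(gt, n_trials_per_cond=40, seed=3)
        valid = grid20.valid_mask()
        mean_hz = np.nanmean(spikes.counts[:, :, valid], axis=(1, 2)) \
            / grid20.bin_ms * 1000.0
        se = np.sqrt(gt.baseline_hz / (40 * valid.sum() * grid20.bin_ms
                                       / 1000.0))
        assert np.all(np.abs(mean_hz - gt.baseline_hz) < 4 * se + 1e-9)

    def test_trial_average_converges_to_rate_as_sqrt_n(self, conditions20,
                                                       grid20):
        gt = make_ground_truth(conditions20, grid20, n_units=20, seed=5)
        rates = gt.rates_hz() * grid20.bin_ms / 1000.0
        valid = grid20.valid_mask()
        errs = []
        for n in (10, 100, 1000):
            spikes = gen_population_spikes(gt, n_trials_per_cond=n, seed=n)
            emp = np.nanmean(spikes.counts, axis=1)
            errs.append(np.sqrt(np.nanmean((emp[:, valid]
                                            - rates[:, valid]) ** 2)))
        # RMSE should shrink ~1/sqrt(10) per decade of trials
        assert errs[1] < errs[0] / 2
        assert errs[2] < errs[1] / 2

    def test_missing_cells_marked_and_nan(self, small_dataset):
        _, _, _, spikes = small_dataset
        u, c = np.argwhere(spikes.missing)[0]
        assert np.isnan(spikes.counts[u, :, c, :]).all()

    def test_single_trial_rejected(self, conditions20, grid20):
        gt = make_ground_truth(conditions20, grid20, n_units=5, seed=0)
        with pytest.raises(ValueError, match="2 trials"):
            gen_population_spikes(gt, n_trials_per_cond=1)

    def test_end_to_end_determinism(self):
        a = generate_dataset(n_conditions=5, n_units=10, n_trials=3, seed=9)
        b = generate_dataset(n_conditions=5, n_units=10, n_trials=3, seed=9)
        ca, cb = a[3].counts, b[3].counts
        assert np.array_equal(ca[np.isfinite(ca)], cb[np.isfinite(cb)])


class TestTrackingError:
    def test_perfect_eye_and_paddle_give_zero_curves(self, conditions20,
                                                     grid20):
        traces, trajs = [], []
        for cond in conditions20:
            traj = simulate_trajectory(cond)
            eye = gen_eye_trace(traj, 0, 0, 0)
            # paddle glued to yf from the start
            from mentalpong.task import PaddleTrace
            times = np.arange(0.0, cond.duration_ms, 16.6)
            pad = PaddleTrace(times=times, paddle_y=np.full_like(times,
                                                                 cond.yf),
                              joystick_voltage=np.full_like(times, 2.5),
                              triggered=np.zeros(len(times), bool))
            eye.paddle = pad
            traces.append(eye)
            trajs.append(traj)
        curves = tracking_error_curves(traces, trajs, grid20)
        ok = curves["eye"]["n"] > 0
        assert np.nanmax(curves["eye"]["mean"][ok]) < 1e-9
        assert np.nanmax(curves["hand"]["mean"][ok]) < 1e-9

    def test_lagged_eye_curve_matches_shift_oracle(self, grid20,
                                                   conditions20):
        lag = 150.0
        traces, trajs, expect = [], [], []
        for c, cond in enumerate(conditions20):
            traj = simulate_trajectory(cond)
            traces.append(gen_eye_trace(traj, lag, 0, 0))
            trajs.append(traj)
            centers = grid20.bin_centers(c)
            bx = np.interp(centers, traj.times, traj.ball_x)
            by = np.interp(centers, traj.times, traj.ball_y)
            lx = np.interp(np.maximum(centers - lag, 0), traj.times,
                           traj.ball_x)
            ly = np.interp(np.maximum(centers - lag, 0), traj.times,
                           traj.ball_y)
            row = np.full(grid20.max_bins, np.nan)
            row[:grid20.n_bins[c]] = np.hypot(lx - bx, ly - by)
            expect.append(row)
        curves = tracking_error_curves(traces, trajs, grid20)
        want = np.nanmean(np.array(expect), axis=0)
        ok = curves["eye"]["n"] > 0
        assert np.allclose(curves["eye"]["mean"][ok], want[ok], atol=1e-6)

    def test_mismatched_grid_rejected(self, conditions20, grid20):
        traj = simulate_trajectory(conditions20[0])
        short = BehaviorTraces(eye_times=np.arange(100.0),
                               eye_x=np.zeros(100), eye_y=np.zeros(100))
        with pytest.raises(ValueError, match="ends at"):
            tracking_error_curves([short] * len(conditions20),
                                  [traj] * len(conditions20), grid20)
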