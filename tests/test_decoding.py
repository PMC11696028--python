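"""Static linear readouts, partial correlations, endpoint analyses."""

import numpy as np
import pytest
from scipy import stats

from mentalpong.preprocess import FactorTensor
from mentalpong.decoding import (behavioral_consistency_endpoint,
                                 decode_endpoint_timecourse,
                                 endpoint_estimate_matrix,
                                 evaluate_by_time_epoch, fit_static_readout,
                                 partial_corr, two_stage_endpoint)


def _factors_from_channels(grid, channels, extra_noise=0.0, n_extra=3,
                           seed=0):
    """FactorTensor whose scores literally contain the given channels."""
    rng = np.random.default_rng(seed)
    C, B = grid.n_conditions, grid.max_bins
    layers = [np.asarray(ch, float) for ch in channels]
    for _ in range(n_extra):
        extra = np.full((C, B), np.nan)
        extra[grid.valid_mask()] = rng.standard_normal(
            int(grid.valid_mask().sum()))
        layers.append(extra)
    scores = np.stack(layers)
    if extra_noise > 0:
        noise = rng.standard_normal(scores.shape) * extra_noise
        scores = scores + noise
    F = scores.shape[0]
    return FactorTensor(scores=scores, loading=np.eye(F), grid=grid,
                        n_factors=F)


class TestStaticReadout:
    def test_embedded_target_decoded_perfectly(self, small_dataset):
        conds, grid, gt, _ = small_dataset
        ch = gt.channels
        fa = _factors_from_channels(grid, [ch["ball_x"], ch["ball_y"]])
        target = np.stack([ch["ball_x"], ch["ball_y"]], axis=-1)
        res = fit_static_readout(fa, target, n_splits=10, seed=0)
        assert np.all(res.r > 0.999999)
        assert np.all(res.rmse < 1e-6)

    def test_attenuation_matches_closed_form(self, small_dataset):
        """Additive noise of known variance on a linear embedding gives
        r = sqrt(s2 / (s2 + n2)) on held-out conditions."""
        conds, grid, gt, _ = small_dataset
        bx = gt.channels["ball_x"]
        sigma = 2.0
        fa = _factors_from_channels(grid, [bx], extra_noise=0.0, n_extra=0)
        rng = np.random.default_rng(1)
        fa.scores = fa.scores + rng.standard_normal(fa.scores.shape) * sigma
        res = fit_static_readout(fa, bx, n_splits=100, seed=0)
        s2 = np.nanvar(bx[grid.valid_mask()])
        expect = np.sqrt(s2 / (s2 + sigma ** 2))
        assert res.r.mean() == pytest.approx(expect, abs=0.03)

    def test_splits_never_share_conditions(self, small_dataset):
        conds, grid, gt, _ = small_dataset
        fa = _factors_from_channels(grid, [gt.channels["ball_x"]])
        from sklearn.model_selection import GroupShuffleSplit
        X = fa.scores[:, grid.valid_mask()].T
        groups = np.where(grid.valid_mask())[0]
        gss = GroupShuffleSplit(n_splits=50, train_size=0.5, random_state=0)
        for tr, te in gss.split(X, groups=groups):
            assert not set(groups[tr]) & set(groups[te])

    def test_default_protocol_half_conditions_100_splits(self, small_dataset):
        conds, grid, gt, _ = small_dataset
        fa = _factors_from_channels(grid, [gt.channels["ball_x"]])
        res = fit_static_readout(fa, gt.channels["ball_x"], seed=0)
        assert res.n_splits == 100
        assert res.train_frac == 0.5

    def test_weights_are_bin_independent(self, small_dataset):
        """The static readout is one weight vector applied at every bin."""
        conds, grid, gt, _ = small_dataset
        fa = _factors_from_channels(grid, [gt.channels["ball_x"]])
        res = fit_static_readout(fa, gt.channels["ball_x"], n_splits=5,
                                 seed=0)
        assert res.weights.shape == (5, fa.n_factors + 1, 1)


class TestEpochEvaluation:
    def test_perfect_predictions_score_one_in_both_epochs(self,
                                                          small_dataset):
        conds, grid, gt, _ = small_dataset
        fa = _factors_from_channels(grid, [gt.channels["ball_y"]])
        res = fit_static_readout(fa, gt.channels["ball_y"], n_splits=10,
                                 seed=0)
        ep = evaluate_by_time_epoch(res)
        assert ep["visible"]["r"][0] > 0.999
        assert ep["occluded"]["r"][0] > 0.999

    def test_masked_recomputation_equals_direct_subsetting(self,
                                                           small_dataset):
        conds, grid, gt, _ = small_dataset
        fa = _factors_from_channels(grid, [gt.channels["ball_x"]],
                                    extra_noise=0.5, seed=2)
        res = fit_static_readout(fa, gt.channels["ball_x"], n_splits=20,
                                 seed=0)
        ep = evaluate_by_time_epoch(res)
        m = res.rows_visible & (res.pred_count > 0)
        direct = stats.pearsonr(res.target[m, 0], res.pred_mean[m, 0])[0]
        assert ep["visible"]["r"][0] == pytest.approx(direct, abs=1e-12)


class TestPartialCorr:
    def test_independent_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        y = 0.7 * x + 0.3 * rng.standard_normal(500)
        z = rng.standard_normal(500)
        assert partial_corr(x, y, z) == pytest.approx(
            stats.pearsonr(x, y)[0], abs=0.02)

    def test_prediction_equal_to_covariate_partials_to_zero(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(500)
        y = 0.5 * z + rng.standard_normal(500)
        assert abs(partial_corr(z, y, z)) < 1e-10

    def test_trivariate_gaussian_closed_form(self):
        """rho_xy.z = (0.6 - 0.25) / 0.75 for rho_xy=0.6, rho_xz=rho_yz=0.5."""
        rho = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
        rng = np.random.default_rng(2)
        X = rng.multivariate_normal(np.zeros(3), rho, size=100_000)
        got = partial_corr(X[:, 0], X[:, 1], X[:, 2])
        assert got == pytest.approx((0.6 - 0.25) / (1 - 0.25), abs=0.01)

    def test_collinear_covariate_warns(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="collinear"):
            partial_corr(rng.standard_normal(100), y, y)


class TestEndpointDecoding:
    def test_planted_endpoint_gives_flat_high_curve(self, default_dataset):
        conds, grid, gt, _ = default_dataset
        yf = gt.channels["endpoint_yf"][:, 0]
        fa = _factors_from_channels(grid, [gt.channels["endpoint_yf"]],
                                    extra_noise=0.3, seed=3)
        ed = decode_endpoint_timecourse(fa, yf, n_splits=20, n_shuffles=5,
                                        seed=0)
        ok = np.isfinite(ed.r)
        assert np.nanmin(ed.r[ok][:5]) > 0.8          # high from early bins
        # held-out r under permuted targets is centered near zero (with a
        # small finite-sample negative bias)
        assert np.nanmean(ed.shuffle_r) == pytest.approx(0.0, abs=0.15)

    def test_position_only_code_improves_toward_trial_end(self,
                                                          small_dataset):
        conds, grid, gt, _ = small_dataset
        ch = gt.channels
        yf = ch["endpoint_yf"][:, 0]
        fa = _factors_from_channels(grid, [ch["ball_x"], ch["ball_y"]],
                                    extra_noise=0.2, seed=4)
        ed = decode_endpoint_timecourse(fa, yf, n_splits=20, n_shuffles=0,
                                        seed=0)
        ok = np.isfinite(ed.r)
        rho, p = stats.spearmanr(ed.bins[ok], ed.r[ok])
        assert rho > 0 and p < 0.01

    def test_consistency_of_identical_residuals_is_one(self, small_dataset):
        conds, grid, gt, _ = small_dataset
        yf = gt.channels["endpoint_yf"][:, 0]
        rng = np.random.default_rng(5)
        resid = rng.standard_normal(len(yf))
        paddle = yf + resid
        est = np.repeat((yf + resid)[:, None], 4, axis=1)
        cons = behavioral_consistency_endpoint(est, paddle, yf)
        assert np.allclose(cons, 1.0, atol=1e-10)

    def test_independent_residuals_give_null_consistency(self,
                                                         small_dataset):
        conds, grid, gt, _ = small_dataset
        yf = gt.channels["endpoint_yf"][:, 0]
        rng = np.random.default_rng(6)
        paddle = yf + rng.standard_normal(len(yf))
        est = np.repeat(yf[:, None], 4, axis=1) \
            + rng.standard_normal((len(yf), 4))
        cons = behavioral_consistency_endpoint(est, paddle, yf)
        assert np.all(np.abs(cons) < 2.0 / np.sqrt(len(yf)) + 0.25)

    def test_planted_residual_correlation_recovered(self, default_dataset):
        """A shared noise source between neural estimate and behavior is
        recovered as residual consistency near the planted value."""
        conds, grid, gt, _ = default_dataset
        yf = gt.channels["endpoint_yf"][:, 0]
        rng = np.random.default_rng(7)
        shared = rng.standard_normal(len(yf))
        rho = 0.5
        paddle = yf + shared
        est_resid = (rho * shared[:, None]
                     + np.sqrt(1 - rho ** 2)
                     * rng.standard_normal((len(yf), 6)))
        est = yf[:, None] + est_resid
        cons = behavioral_consistency_endpoint(est, paddle, yf)
        assert np.nanmean(cons) == pytest.approx(rho, abs=0.1)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="3 conditions"):
            behavioral_consistency_endpoint(np.zeros((2, 4)), np.zeros(2),
                                            np.zeros(2))


class TestTwoStage:
    def test_direct_decoder_dominates_two_stage(self, small_dataset):
        """Data-processing check: compressing to decoded intermediates
        cannot beat the direct endpoint decoder."""
        conds, grid, gt, _ = small_dataset
        ch = gt.channels
        yf = ch["endpoint_yf"][:, 0]
        fa = _factors_from_channels(grid, [ch["ball_x"], ch["ball_y"],
                                           ch["ball_dy"]],
                                    extra_noise=0.2, seed=8)
        inter = np.stack([ch["ball_x"], ch["ball_y"]], axis=-1)
        out = two_stage_endpoint(fa, inter, yf, n_splits=20, seed=0)
        ok = np.isfinite(out["two_stage_r"]) & np.isfinite(out["direct_r"])
        assert np.nanmean(out["direct_r"][ok]) >= \
            np.nanmean(out["two_stage_r"][ok]) - 0.05

    def test_velocity_mediation_beats_position_only(self, small_dataset):
        """When yf depends on velocity, adding decoded velocity as an
        intermediary improves late-trial endpoint prediction."""
        conds, grid, gt, _ = small_dataset
        ch = gt.channels
        yf = ch["endpoint_yf"][:, 0]
        fa = _factors_from_channels(grid, [ch["ball_x"], ch["ball_y"],
                                           ch["ball_dy"]],
                                    extra_noise=0.1, seed=9)
        pos = np.stack([ch["ball_x"], ch["ball_y"]], axis=-1)
        posvel = np.stack([ch["ball_x"], ch["ball_y"], ch["ball_dx"],
                           ch["ball_dy"]], axis=-1)
        r_pos = two_stage_endpoint(fa, pos, yf, n_splits=20,
                                   seed=0)["two_stage_r"]
        r_pv = two_stage_endpoint(fa, posvel, yf, n_splits=20,
                                  seed=0)["two_stage_r"]
        ok = np.isfinite(r_pos) & np.isfinite(r_pv)
        # restrict to bins mid-trial where velocity information matters
        assert np.nanmean(r_pv[ok]) > np.nanmean(r_pos[ok])

    def test_oracle_intermediates_match_kinematic_regression(self,
                                                             small_dataset):
        conds, grid, gt, _ = small_dataset
        ch = gt.channels
        yf = ch["endpoint_yf"][:, 0]
        # factors literally contain position+velocity -> stage 1 is exact
        fa = _factors_from_channels(grid,
                                    [ch["ball_x"], ch["ball_y"],
                                     ch["ball_dx"], ch["ball_dy"]],
                                    n_extra=0)
        posvel = np.stack([ch["ball_x"], ch["ball_y"], ch["ball_dx"],
                           ch["ball_dy"]], axis=-1)
        out = two_stage_endpoint(fa, posvel, yf, n_splits=20, seed=0)
        late = np.isfinite(out["two_stage_r"])
        # late-trial kinematics determine yf almost exactly
        assert np.nanmean(out["two_stage_r"][late][-5:]) > 0.9
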