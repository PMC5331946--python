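import numpy as np
import pandas as pd
import pytest

import serolearn as sl
from serolearn.bold import (
    HRFSpec,
    TimecourseResult,
    _shifted_kernel,
    build_fglm_design,
    canonical_hrf,
    extract_epochs,
    loo_hrf_summary,
    roi_panel_stats,
    timepoint_regression,
    trial_regressor,
)
from serolearn.simulate import BoldSeries, simulate_roi_bold


class TestCanonicalHRF:
    def test_peak_at_gamma_mode(self):
        spec = HRFSpec(dt=0.01)
        t, k = canonical_hrf(spec)
        assert t[np.argmax(k)] == pytest.approx(40 / 7, abs=0.02)
        assert spec.peak_time == pytest.approx(40 / 7)

    def test_nonnegative_and_unit_mass(self):
        t, k = canonical_hrf(HRFSpec(dt=0.1))
        assert np.all(k >= 0)
        assert np.trapezoid(k, t) == pytest.approx(1.0, abs=0.01)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(HRFSpec(dt=0.0))


class TestFGLMDesign:
    def test_fglm2_has_exactly_seven_regressors(self, session, trace):
        X = build_fglm_design(session, trace, "fGLM2")
        assert X.shape == (session.n_trials, 7)

    def test_fglm2_reduced_drops_outcome_columns(self, session, trace):
        X = build_fglm_design(session, trace, "fGLM2_reduced")
        assert "rew_outcome_rel" not in X.columns
        assert "eff_outcome_rel" not in X.columns
        assert X.shape[1] == 5

    def test_reward_type_pe_hand_check(self, session, trace):
        x = trial_regressor(session, trace, "reward_type_pe")
        for t in (0, 5, 50):
            code = 1.0 if session.reward_type[t] == "real" else 0.0
            p = session.displayed_prob[session.choice[t], t]
            assert x[t] == pytest.approx(code - p)

    def test_columns_are_zscored(self, session, trace):
        X = build_fglm_design(session, trace, "fGLM1").to_numpy()
        assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(X.std(axis=0), 1, atol=1e-12)

    def test_unknown_spec_raises(self, session, trace):
        with pytest.raises(ValueError):
            build_fglm_design(session, trace, "fGLM7")


class TestExtractEpochs:
    def _bold(self, signal, tr=2.0):
        return BoldSeries(tr_s=tr, signal=np.asarray(signal, float),
                          onsets=np.array([10.0, 40.0]), planted_betas={},
                          noise_sd=0.0, ar1_rho=0.0)

    def test_grid_arithmetic(self):
        rng = np.random.default_rng(0)
        b = self._bold(rng.normal(size=60))
        ep = extract_epochs(b, window_s=20.0, upsample=10)
        assert ep.epochs.shape[1] == 101
        assert ep.times[1] - ep.times[0] == pytest.approx(0.2)

    def test_constant_series_warns_and_zeroes(self):
        b = self._bold(np.ones(60))
        with pytest.warns(UserWarning, match="constant"):
            ep = extract_epochs(b, window_s=10.0)
        assert np.allclose(ep.epochs, 0.0)

    def test_no_op_resampling_at_shared_grid_points(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=60)
        b = self._bold(sig)
        ep = extract_epochs(b, window_s=10.0, upsample=1)
        z = (sig - sig.mean()) / sig.std()
        np.testing.assert_allclose(ep.epochs[0], z[5:11], atol=1e-12)

    def test_epoch_beyond_series_dropped_with_warning(self):
        b = self._bold(np.random.default_rng(2).normal(size=25))
        with pytest.warns(UserWarning, match="dropped"):
            ep = extract_epochs(b, window_s=20.0)
        assert ep.n_trials == 1


class TestTimepointRegression:
    def test_noise_floor(self):
        rng = np.random.default_rng(3)
        n_trials = 100
        from serolearn.bold import EpochMatrix
        ep = EpochMatrix(rng.normal(size=(n_trials, 21)),
                         np.linspace(0, 4, 21), np.arange(n_trials))
        design = pd.DataFrame(rng.normal(size=(n_trials, 3)),
                              columns=list("abc"))
        tc = timepoint_regression(ep, design)
        assert np.mean(np.abs(tc.betas.to_numpy())) < 2 / np.sqrt(n_trials)

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(4)
        from serolearn.bold import EpochMatrix
        ep = EpochMatrix(rng.normal(size=(50, 5)), np.linspace(0, 1, 5),
                         np.arange(50))
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            timepoint_regression(ep, design)

    def test_noiseless_round_trip_matches_hrf_shape(self, session, trace):
        bold = simulate_roi_bold(session, trace, {"rpe_chosen": 1.0},
                                 noise=(0.0, 0.3),
                                 rng=np.random.default_rng(5))
        ep = extract_epochs(bold, window_s=20.0)
        design = build_fglm_design(session, trace, "fGLM2")
        tc = timepoint_regression(ep, design)
        beta = tc.series("rpe_chosen")
        peak_t = tc.times[np.argmax(np.abs(beta))]
        assert 4.0 <= peak_t <= 12.0
        kern = _shifted_kernel(tc.times, peak_t, HRFSpec())
        cos = np.dot(kern, beta) / np.linalg.norm(kern) / np.linalg.norm(beta)
        assert cos > 0.99


def _kernel_timecourses(n, peak_at=8.0, scale=1.0, times=None):
    times = np.arange(0, 20.0001, 0.2) if times is None else times
    k = _shifted_kernel(times, peak_at, HRFSpec())
    return [TimecourseResult(pd.DataFrame({"rpe_chosen": scale * k}), times,
                             f"p{i}") for i in range(n)]


class TestLOOSummary:
    def test_self_alignment_on_identical_kernels(self):
        tcs = _kernel_timecourses(5, peak_at=8.0)
        scalars = loo_hrf_summary(tcs, "rpe_chosen")
        assert np.allclose(scalars, scalars[0])
        assert scalars[0] > 0

    def test_sign_antisymmetry(self):
        tcs = _kernel_timecourses(5, peak_at=8.0)
        neg = _kernel_timecourses(5, peak_at=8.0, scale=-1.0)
        s_pos = loo_hrf_summary(tcs, "rpe_chosen")
        s_neg = loo_hrf_summary(neg, "rpe_chosen")
        np.testing.assert_allclose(s_neg, -s_pos)

    def test_leave_one_out_ignores_own_series(self):
        """Perturbing the left-out participant must not move the chosen peak."""
        tcs = _kernel_timecourses(6, peak_at=9.0)
        times = tcs[0].times
        spiked = _shifted_kernel(times, 7.0, HRFSpec()) * 50
        tcs[0] = TimecourseResult(pd.DataFrame({"rpe_chosen": spiked}),
                                  times, "p0")
        scalars = loo_hrf_summary(tcs, "rpe_chosen")
        # participant 0's scalar projects the 9-s-aligned kernel (from the
        # others) onto its own 7-s series -- cross-kernel overlap, not the
        # 7-s self-alignment value
        k9 = _shifted_kernel(times, 9.0, HRFSpec())
        assert scalars[0] == pytest.approx(float(np.sum(k9 * spiked)))

    def test_group_restriction(self):
        a = _kernel_timecourses(3, peak_at=7.0)
        b = _kernel_timecourses(3, peak_at=11.0, scale=2.0)
        scalars = loo_hrf_summary(a + b, "rpe_chosen",
                                  groups=["a"] * 3 + ["b"] * 3)
        assert np.allclose(scalars[:3], scalars[0])
        assert np.allclose(scalars[3:], scalars[3])
        assert scalars[3] > scalars[0]

    def test_too_few_participants_raise(self):
        tcs = _kernel_timecourses(2)
        with pytest.raises(ValueError, match="participants"):
            loo_hrf_summary(tcs, "rpe_chosen")

    def test_peak_window_outside_epoch_raises(self):
        times = np.arange(0, 8.0001, 0.2)
        tcs = _kernel_timecourses(4, peak_at=6.0, times=times)
        with pytest.raises(ValueError, match="window"):
            loo_hrf_summary(tcs, "rpe_chosen", peak_window_s=(6.0, 12.0))


class TestRoiPanel:
    def test_bonferroni_threshold_for_six_rois(self):
        rng = np.random.default_rng(6)
        scalars = pd.DataFrame(rng.normal(size=(20, 6)),
                               columns=[f"roi{i}" for i in range(6)])
        groups = ["a"] * 10 + ["b"] * 10
        out = roi_panel_stats(scalars, groups)
        assert out["bonferroni_threshold"] == pytest.approx(0.05 / 6)
        assert out["bonferroni_threshold"] == pytest.approx(0.00833, abs=1e-4)

    def test_single_roi_anova_equals_t_squared(self):
        rng = np.random.default_rng(7)
        scalars = pd.DataFrame({"roi0": rng.normal(size=20)})
        groups = ["a"] * 10 + ["b"] * 10
        out = roi_panel_stats(scalars, groups)
        t = out["per_roi"]["roi0"]["ttest"]["t"]
        assert out["anova"]["F"] == pytest.approx(t ** 2, abs=1e-8)

    def test_missing_cells_raise(self):
        scalars = pd.DataFrame({"roi0": [1.0, np.nan, 2.0, 3.0]})
        with pytest.raises(ValueError):
            roi_panel_stats(scalars, ["a", "a", "b", "b"])
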