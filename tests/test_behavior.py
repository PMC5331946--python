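import numpy as np
import pandas as pd
import pytest

import serolearn as sl
from serolearn.behavior import (
    build_design,
    code_stay_switch,
    fit_linear,
    fit_logistic,
    group_contrast,
    interference_contrast,
    interference_score,
    quartile_split,
    RegressionResult,
)
from tests.conftest import make_session


class TestCodeStaySwitch:
    def test_always_repeat_agent_has_constant_stay(self, schedule):
        sess = make_session(schedule, [0] * schedule.n_trials,
                            ["real"] * schedule.n_trials)
        tr = sl.run_rw_learner(sess, (0.4, 0.4))
        base = code_stay_switch(sess, tr)
        assert np.all(base["stay"] == 1.0)

    def test_option_relabel_flips_relative_columns(self, session, trace):
        import copy
        base = code_stay_switch(session, trace)
        flipped = copy.copy(session)
        flipped.choice = 1 - session.choice
        tr2 = sl.run_rw_learner(flipped, (0.35, 0.45))
        tr1 = sl.run_rw_learner(session, (0.35, 0.45))
        b1 = code_stay_switch(session, tr1)
        b2 = code_stay_switch(flipped, tr2)
        # stay indicator unchanged; every relative regressor sign-flips
        np.testing.assert_allclose(b2["stay"], b1["stay"])
        for col in ("rel_prob", "rel_pred_rew", "rel_pred_eff", "rel_rpe",
                    "rel_epe"):
            np.testing.assert_allclose(b2[col], -b1[col], atol=1e-12)

    def test_hand_built_four_trial_example(self):
        cfg = sl.ScheduleConfig(n_trials=4, drift_sd=0.0)
        sch = sl.generate_schedule(cfg, seed=3)
        sch.reward_mag[:] = [[0.8] * 4, [0.2] * 4]
        sch.effort_mag[:] = [[0.4] * 4, [0.6] * 4]
        sess = make_session(sch, [0, 0, 1, 1],
                            ["real", "hypothetical", "real", "real"])
        tr = sl.run_rw_learner(sess, (0.5, 0.5))
        base = code_stay_switch(sess, tr)
        # trial 3 (0-based t=2): stay option = choice[1] = 0
        # rpe at t=1 per option: outcome - pred; preds after one 0.5-update
        # from 0.5: [0.65, 0.35]; rpes at t=1: [0.15, -0.15]
        row = base[base["trial"] == 3].iloc[0]
        assert row["rel_rpe"] == pytest.approx(0.15 - (-0.15))
        assert row["stay"] == 0.0  # chose option 1 after option 0
        assert row["reward_type_prev"] == -1.0  # trial 2 was hypothetical


class TestQuartileSplit:
    def test_counts_on_120_trials(self):
        rng = np.random.default_rng(0)
        lab = quartile_split(rng.normal(size=120))
        assert (lab == "high").sum() == 30
        assert (lab == "low").sum() == 30
        assert (lab == "mid").sum() == 60

    def test_tie_break_is_stable(self):
        lab = quartile_split(np.zeros(8))
        assert (lab[:2] == "low").all() and (lab[-2:] == "high").all()

    def test_too_few_trials_raise(self):
        with pytest.raises(ValueError):
            quartile_split(np.arange(7))


class TestBuildDesign:
    def test_bglm2_shape(self, session, trace):
        X, y = build_design(session, trace, "bGLM2")
        assert X.shape == (119, 8)
        assert len(y) == 119
        assert list(X.columns[:2]) == ["rpe_x_rewardtype", "rpe_x_epe"]

    @pytest.mark.parametrize("name,ncols", [
        ("bGLM1", 4), ("bGLM2", 8), ("bGLM3a", 8), ("bGLM3b", 8),
        ("bGLM4", 6), ("bGLM5", 8),
    ])
    def test_column_counts(self, session, trace, name, ncols):
        X, y = build_design(session, trace, name)
        assert X.shape[1] == ncols

    def test_zscore_contract(self, session, trace):
        X, _ = build_design(session, trace, "bGLM1")
        arr = X.to_numpy()
        assert np.allclose(arr.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(arr.std(axis=0), 1.0, atol=1e-10)

    def test_conditional_columns_zero_off_support(self, session, trace):
        X, _ = build_design(session, trace, "bGLM3a")
        real = X["rpe_real"].to_numpy()
        hypo = X["rpe_hypo"].to_numpy()
        # supports are disjoint
        assert np.all((real == 0) | (hypo == 0))

    def test_unknown_design_raises(self, session, trace):
        with pytest.raises(ValueError):
            build_design(session, trace, "bGLM9")

    def test_eglm1_uses_all_trials(self, session, trace):
        X, y = build_design(session, trace, "eGLM1")
        assert X.shape == (120, 4)
        assert len(y) == 120


class TestFitLogistic:
    def test_null_design_recovers_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        y = rng.integers(0, 2, size=10_000).astype(float)
        res = fit_logistic(X, y)
        assert np.all(np.abs(res.coefficients[list("abc")]) < 0.05)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        logits = 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(400) < 1 / (1 + np.exp(-logits))).astype(float)
        res = fit_logistic(X, y)

        def nll(b0, b1, b2):
            z = b0 + b1 * X["a"] + b2 * X["b"]
            p = 1 / (1 + np.exp(-z))
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        grid = np.arange(-1.5, 1.51, 0.01)
        best = min(((nll(res.coefficients["intercept"], b1, b2), b1, b2)
                    for b1 in grid for b2 in grid))
        assert res.coefficients["a"] == pytest.approx(best[1], abs=0.01)
        assert res.coefficients["b"] == pytest.approx(best[2], abs=0.01)

    def test_generative_recovery(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["a", "b"])
        z = 0.5 * X["a"] - 0.3 * X["b"]
        y = (rng.random(5000) < 1 / (1 + np.exp(-z))).astype(float)
        res = fit_logistic(X, y)
        assert res.coefficients["a"] == pytest.approx(0.5, abs=0.1)
        assert res.coefficients["b"] == pytest.approx(-0.3, abs=0.1)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.linspace(-1, 1, 50)
        X = pd.DataFrame({"a": x})
        y = (x > 0).astype(float)
        res = fit_logistic(X, y)
        assert not res.converged
        assert np.all(np.abs(res.coefficients) <= 20.0)

    def test_nonbinary_outcome_raises(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(ValueError):
            fit_logistic(X, np.arange(20.0))


class TestFitLinear:
    def test_exact_fit(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = X["b"].to_numpy()
        res = fit_linear(X, y)
        assert res.coefficients["b"] == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["a"] == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "dup": a, "c": rng.normal(size=50)})
        with pytest.raises(ValueError, match="dup"):
            fit_linear(X, rng.normal(size=50))

    def test_planted_exertion_coefficients_recovered(self, schedule):
        from serolearn.simulate import ExertionCoefficients, simulate_effort_exertion
        sess = sl.simulate_agent(schedule, sl.GenerativeAgentParams(),
                                 np.random.default_rng(6))
        coef = ExertionCoefficients(base=4.0, chosen_reward=0.5,
                                    irrelevant_reward=0.0, noise_sd=0.0)
        sess.clicking_rate = simulate_effort_exertion(
            sess, coef, np.random.default_rng(7))
        tr = sl.run_bayes_learner(sess)
        X, y = build_design(sess, tr, "eGLM1")
        res = fit_linear(X, y)
        t = np.arange(sess.n_trials)
        chosen = sess.reward_outcome[sess.choice, t]
        # z-scored design: the raw weight 0.5 maps to 0.5 * sd(chosen reward)
        assert res.coefficients["chosen_reward"] == pytest.approx(
            0.5 * chosen.std(), abs=1e-8)


class TestGroupStats:
    def _fake_result(self, b1, b2):
        s = pd.Series({"intercept": 0.0, "rpe_x_rewardtype": b1, "rpe_x_epe": b2})
        return RegressionResult("p", "bGLM2", s, True, 119)

    def test_interference_score_sign_convention(self):
        r = self._fake_result(0.4, -0.2)
        assert interference_score(r) == pytest.approx(0.5 * (0.4 + 0.2))

    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=10)
        results = [self._fake_result(v, -v) for v in np.concatenate([vals, vals])]
        groups = ["a"] * 10 + ["b"] * 10
        out = interference_contrast(results, groups)
        assert out["group_difference"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["group_difference"]["p"] == pytest.approx(1.0)

    def test_ttest_null(self):
        vals = np.concatenate([np.arange(5.0), np.arange(5.0)])
        out = group_contrast(vals, ["a"] * 5 + ["b"] * 5, "ttest")
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_welch_df_below_pooled(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 5, 14)])
        groups = ["a"] * 15 + ["b"] * 14
        w = group_contrast(vals, groups, "welch_ttest")
        p = group_contrast(vals, groups, "ttest")
        assert w["df"] < p["df"] == 27

    def test_ttest_power_matches_analytic(self):
        """Rejection rate at alpha=.05, n=15/14, effect 1 SD ~ analytic 0.74."""
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = np.concatenate([rng.normal(1, 1, 15), rng.normal(0, 1, 14)])
            out = group_contrast(vals, ["a"] * 15 + ["b"] * 14, "ttest")
            rejections += out["p"] < 0.05
        assert abs(rejections / n_rep - 0.74) < 0.05

    def test_mixed_anova_single_condition_equals_t_squared(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame({"c1": rng.normal(size=20)})
        groups = ["a"] * 10 + ["b"] * 10
        aov = group_contrast(vals, groups, "mixed_anova")
        tt = group_contrast(vals["c1"].to_numpy(), groups, "ttest")
        assert aov["F"] == pytest.approx(tt["t"] ** 2, abs=1e-8)

    def test_mixed_anova_runs_with_conditions(self):
        rng = np.random.default_rng(12)
        vals = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        groups = ["a"] * 10 + ["b"] * 10
        out = group_contrast(vals, groups, "mixed_anova")
        assert {"F", "df1", "df2", "p", "interaction_F"} <= set(out)
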