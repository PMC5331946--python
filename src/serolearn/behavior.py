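"""Stay/switch logistic regressions, effort-exertion regression, group contrasts.

Behavioral learning is measured by how prediction errors on trial t-1 shift the
decision to stay with, or switch away from, the previous choice on trial t.
Option-level quantities enter in the relative "stay minus switch" frame: value
for the previously chosen option minus value for the alternative, mirroring the
chosen-minus-unchosen convention of the fMRI analysis.

Designs
-------
bGLM1   task validation: relative probability, relative learnt reward/effort
        predictions, previous reward type.
bGLM2   interference: interactions RPE x reward-type and RPE x EPE (formed
        after z-scoring each factor) plus main-effect confounds.
bGLM3a  RPE (and EPE) split by real vs. hypothetical reward.
bGLM3b  RPE split by favorable / unfavorable / mid relative-EPE quartiles.
bGLM4   overall learning: probability, predictions, RPE, EPE, reward type.
bGLM5   effort-learning mirror of bGLM3b (EPE split by RPE quartiles).
eGLM1   linear regression of clicking rate on reward factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .learners import REWARD_TYPE_DESIGN_CODES, LearnerTrace

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import BehavioralSession

__all__ = [
    "DesignSpec", "RegressionResult", "code_stay_switch", "build_design",
    "quartile_split", "fit_logistic", "fit_linear", "interference_contrast",
    "group_contrast", "DESIGN_NAMES",
]

DESIGN_NAMES = ("bGLM1", "bGLM2", "bGLM3a", "bGLM3b", "bGLM4", "bGLM5", "eGLM1")

#: coefficient magnitude cap reported for separable logistic fits
SEPARATION_CAP = 20.0


@dataclass(frozen=True)
class DesignSpec:
    name: str
    outcome: str                 # "stay" | "clicking_rate"
    columns: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...] = ()


@dataclass
class RegressionResult:
    participant_id: str
    design_name: str
    coefficients: pd.Series      # includes "intercept"
    converged: bool
    n_obs: int

    def __getitem__(self, name: str) -> float:
        return float(self.coefficients[name])


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd <= 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def quartile_split(values: np.ndarray) -> np.ndarray:
    """Label each value 'high' (top quartile), 'low' (bottom), or 'mid'.

    Exactly ``n // 4`` trials fall in each extreme quartile; ties are broken by
    a stable sort on trial index.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError(f"quartile split needs >= 8 usable trials, got {n}")
    q = n // 4
    order = np.argsort(values, kind="stable")
    labels = np.full(n, "mid", dtype=object)
    labels[order[:q]] = "low"
    labels[order[n - q:]] = "high"
    return labels


def code_stay_switch(session: "BehavioralSession",
                     trace: LearnerTrace) -> pd.DataFrame:
    """Stay indicator and relative (stay-minus-switch) regressor columns.

    Rows cover trials 2..n (trial 1 has no previous choice).  The "stay"
    option on row t is the option chosen on trial t-1.  Two prediction frames
    are provided: ``rel_pred_*`` are the learner's current predictions for
    trial t (already updated with trial t-1's outcome; used by the task
    validation design), while ``rel_pred_*_prev`` are the pre-update
    predictions that entered trial t-1 (used by the interference designs, so
    that the separate PE columns carry the update itself).  PE columns are
    trial t-1's prediction errors, which in the relative frame equal
    chosen-minus-unchosen PE of the previous trial.
    """
    n = session.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials")
    t = np.arange(1, n)           # current trials (0-based)
    stay_opt = session.choice[t - 1]
    sw_opt = 1 - stay_opt
    stay = (session.choice[t] == stay_opt).astype(float)
    rel = lambda arr, idx: arr[stay_opt, idx] - arr[sw_opt, idx]
    rt_code = np.array([REWARD_TYPE_DESIGN_CODES[r] for r in session.reward_type])
    return pd.DataFrame({
        "trial": t + 1,
        "stay": stay,
        "rel_prob": rel(session.displayed_prob, t),
        "rel_pred_rew": rel(trace.pred_reward, t),
        "rel_pred_eff": rel(trace.pred_effort, t),
        "rel_pred_rew_prev": rel(trace.pred_reward, t - 1),
        "rel_pred_eff_prev": rel(trace.pred_effort, t - 1),
        "rel_rpe": trace.rpe_chosen[t - 1] - trace.rpe_unchosen[t - 1],
        "rel_epe": trace.epe_chosen[t - 1] - trace.epe_unchosen[t - 1],
        "reward_type_prev": rt_code[t - 1],
        "clicking_rate": session.clicking_rate[t],
    })


def _conditional(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Regressor restricted to qualifying trials: z-scored on support, 0 off it."""
    out = np.zeros_like(x, dtype=float)
    if mask.sum() >= 2:
        out[mask] = zscore(x[mask])
    return out


def build_design(session: "BehavioralSession", trace: LearnerTrace,
                 spec: str | DesignSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (z-scored columns) and outcome vector for a named GLM."""
    name = spec if isinstance(spec, str) else spec.name
    if name not in DESIGN_NAMES:
        raise ValueError(f"unknown design '{name}'; expected one of {DESIGN_NAMES}")
    base = code_stay_switch(session, trace)
    z = {c: zscore(base[c].to_numpy()) for c in
         ("rel_prob", "rel_pred_rew", "rel_pred_eff", "rel_pred_rew_prev",
          "rel_pred_eff_prev", "rel_rpe", "rel_epe", "reward_type_prev")}
    real_prev = base["reward_type_prev"].to_numpy() > 0

    if name == "bGLM1":
        X = pd.DataFrame({
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew"],
            "rel_pred_eff": z["rel_pred_eff"],
            "reward_type_prev": z["reward_type_prev"],
        })
    elif name == "bGLM2":
        X = pd.DataFrame({
            "rpe_x_rewardtype": z["rel_rpe"] * z["reward_type_prev"],
            "rpe_x_epe": z["rel_rpe"] * z["rel_epe"],
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew_prev"],
            "rel_pred_eff": z["rel_pred_eff_prev"],
            "reward_type_prev": z["reward_type_prev"],
            "rel_rpe": z["rel_rpe"], "rel_epe": z["rel_epe"],
        })
    elif name == "bGLM3a":
        rpe = base["rel_rpe"].to_numpy()
        epe = base["rel_epe"].to_numpy()
        X = pd.DataFrame({
            "rpe_real": _conditional(rpe, real_prev),
            "rpe_hypo": _conditional(rpe, ~real_prev),
            "epe_real": _conditional(epe, real_prev),
            "epe_hypo": _conditional(epe, ~real_prev),
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew_prev"],
            "rel_pred_eff": z["rel_pred_eff_prev"],
            "reward_type_prev": z["reward_type_prev"],
        })
    elif name == "bGLM3b":
        rpe = base["rel_rpe"].to_numpy()
        lab = quartile_split(base["rel_epe"].to_numpy())
        X = pd.DataFrame({
            "rpe_high_epe": _conditional(rpe, lab == "high"),
            "rpe_low_epe": _conditional(rpe, lab == "low"),
            "rpe_mid_epe": _conditional(rpe, lab == "mid"),
            "rel_epe": z["rel_epe"],
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew_prev"],
            "rel_pred_eff": z["rel_pred_eff_prev"],
            "reward_type_prev": z["reward_type_prev"],
        })
    elif name == "bGLM4":
        X = pd.DataFrame({
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew_prev"],
            "rel_pred_eff": z["rel_pred_eff_prev"], "rel_rpe": z["rel_rpe"],
            "rel_epe": z["rel_epe"],
            "reward_type_prev": z["reward_type_prev"],
        })
    elif name == "bGLM5":
        epe = base["rel_epe"].to_numpy()
        lab = quartile_split(base["rel_rpe"].to_numpy())
        X = pd.DataFrame({
            "epe_high_rpe": _conditional(epe, lab == "high"),
            "epe_low_rpe": _conditional(epe, lab == "low"),
            "epe_mid_rpe": _conditional(epe, lab == "mid"),
            "rel_rpe": z["rel_rpe"],
            "rel_prob": z["rel_prob"], "rel_pred_rew": z["rel_pred_rew_prev"],
            "rel_pred_eff": z["rel_pred_eff_prev"],
            "reward_type_prev": z["reward_type_prev"],
        })
    else:  # eGLM1 -- clicking-rate regression on all trials
        t = np.arange(session.n_trials)
        chosen_rew = session.reward_outcome[session.choice, t]
        unchosen_rew = session.reward_outcome[1 - session.choice, t]
        chosen_eff = session.effort_outcome[session.choice, t]
        rt = np.array([1.0 if r == "real" else 0.0 for r in session.reward_type])
        X = pd.DataFrame({
            "chosen_reward": zscore(chosen_rew),
            "unchosen_reward": zscore(unchosen_rew),
            "reward_type": zscore(rt),
            "chosen_effort": zscore(chosen_eff),
        })
        return X, session.clicking_rate.astype(float)

    keep = [c for c in X.columns if X[c].to_numpy().std() > 1e-12]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"{name}: constant columns dropped: {dropped}")
        X = X[keep]
    return X, base["stay"].to_numpy()


def fit_logistic(design: pd.DataFrame, outcome: np.ndarray,
                 participant_id: str = "", design_name: str = "") -> RegressionResult:
    """Maximum-likelihood logistic regression with separation handling.

    Backed by statsmodels' IRLS-style Newton fit; perfect separation (or
    runaway coefficients) is reported as ``converged=False`` with coefficients
    capped in magnitude rather than raised as an error.
    """
    outcome = np.asarray(outcome, dtype=float)
    if not set(np.unique(outcome)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"need n_obs > columns + 1; got {n} rows, {k} columns")
    X = sm.add_constant(design.to_numpy(dtype=float), prepend=True)
    names = ["intercept"] + list(design.columns)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(outcome, X).fit(disp=0, maxiter=100, tol=1e-10)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            params = np.zeros(X.shape[1])
            converged = False
    if np.any(np.abs(params) > SEPARATION_CAP):
        converged = False
        params = np.clip(params, -SEPARATION_CAP, SEPARATION_CAP)
    return RegressionResult(participant_id, design_name,
                            pd.Series(params, index=names), converged, n)


def fit_linear(design: pd.DataFrame, outcome: np.ndarray,
               participant_id: str = "", design_name: str = "") -> RegressionResult:
    """Ordinary least squares; rank deficiency raises, naming collinear columns."""
    X = sm.add_constant(design.to_numpy(dtype=float), prepend=True)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n_obs > columns; got {n} rows, {k} columns")
    if np.linalg.matrix_rank(X) < k:
        r = np.corrcoef(design.to_numpy(dtype=float), rowvar=False)
        iu = np.triu_indices_from(r, k=1)
        worst = np.argmax(np.abs(r[iu]))
        i, j = iu[0][worst], iu[1][worst]
        raise ValueError(
            "rank-deficient design; most collinear columns: "
            f"'{design.columns[i]}' and '{design.columns[j]}' "
            f"(|r| = {abs(r[i, j]):.3f})")
    res = sm.OLS(np.asarray(outcome, dtype=float), X).fit()
    names = ["intercept"] + list(design.columns)
    return RegressionResult(participant_id, design_name,
                            pd.Series(np.asarray(res.params), index=names),
                            True, n)


def interference_score(result: RegressionResult) -> float:
    """Mean interference across the two bGLM2 interaction weights.

    Reward-type interference makes the RPE x reward-type weight positive and
    the RPE x EPE weight negative, so the combined score averages the first
    with the sign-reversed second (the same sign convention used for display).
    """
    return 0.5 * (result["rpe_x_rewardtype"] - result["rpe_x_epe"])


def interference_contrast(results: list[RegressionResult],
                          groups: list[str]) -> dict:
    """Group statistics on the bGLM2 interference scores.

    Returns per-group one-sample t tests against zero and the between-group
    comparison as both a two-sample t and the equivalent one-way F = t**2.
    """
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    scores = np.array([interference_score(r) for r in results])
    by = {g: scores[np.array(groups) == g] for g in labels}
    if any(len(v) == 0 for v in by.values()):
        raise ValueError("both groups must be non-empty")
    out = {"groups": labels, "scores": {g: by[g].tolist() for g in labels}}
    for g in labels:
        t, p = stats.ttest_1samp(by[g], 0.0)
        out[g] = {"mean": float(by[g].mean()), "t": float(t),
                  "df": len(by[g]) - 1, "p": float(p)}
    t, p = stats.ttest_ind(by[labels[0]], by[labels[1]])
    df = len(scores) - 2
    out["group_difference"] = {
        "t": float(t), "df": df, "p": float(p),
        "F": float(t ** 2), "df1": 1, "df2": df,
        "mean_diff": float(by[labels[0]].mean() - by[labels[1]].mean()),
    }
    return out


def group_contrast(values, groups, design: str = "ttest") -> dict:
    """Two-sample t (pooled or Welch) or mixed group x condition ANOVA.

    ``values`` is a 1-D array for t tests, or a (participants x conditions)
    DataFrame for ``design='mixed_anova'`` (between factor: group, within
    factor: condition; Greenhouse-Geisser correction reported when the within
    factor has more than two levels).
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    if design in ("ttest", "welch_ttest"):
        values = np.asarray(values, dtype=float)
        a, b = values[groups == labels[0]], values[groups == labels[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group")
        equal_var = design == "ttest"
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if equal_var:
            df = len(a) + len(b) - 2
        else:  # Welch-Satterthwaite
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        return {"design": design, "t": float(t), "df": float(df), "p": float(p)}
    if design == "mixed_anova":
        import pingouin as pg
        df_wide = pd.DataFrame(values)
        n_cond = df_wide.shape[1]
        if df_wide.shape[0] != len(groups):
            raise ValueError("values rows must match groups length")
        counts = pd.Series(groups).value_counts()
        if counts.min() < 2:
            raise ValueError("need >= 2 observations per group")
        if n_cond == 1:
            # degenerate within factor: the group effect is the two-sample t
            res = group_contrast(df_wide.iloc[:, 0].to_numpy(), groups, "ttest")
            return {"design": "mixed_anova", "F": res["t"] ** 2,
                    "df1": 1, "df2": res["df"], "p": res["p"],
                    "greenhouse_geisser_eps": 1.0}
        long = df_wide.copy()
        long["group"] = groups
        long["subject"] = np.arange(len(groups))
        long = long.melt(id_vars=["group", "subject"], var_name="condition",
                         value_name="value")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=long, dv="value", within="condition",
                                 between="group", subject="subject",
                                 correction=True)
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        row = aov[aov["Source"] == "group"].iloc[0]
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        within = aov[aov["Source"] == "condition"].iloc[0]
        eps = float(within["eps"]) if "eps" in aov.columns else np.nan
        return {
            "design": "mixed_anova",
            "F": float(row["F"]), "df1": float(row["DF1"]),
            "df2": float(row["DF2"]), "p": float(row[pcol]),
            "interaction_F": float(inter["F"]),
            "interaction_p": float(inter[pcol]),
            "greenhouse_geisser_eps": eps,
        }
    raise ValueError(f"unknown design '{design}'")
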