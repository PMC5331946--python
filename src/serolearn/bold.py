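"""ROI BOLD time-course analysis with leave-one-out HRF peak alignment.

Per-trial parametric regressors (prediction errors, outcomes, reward-type PE)
are built from a session and a learner trace.  The ROI series is z-scored,
upsampled tenfold by linear interpolation and cut into epochs time-locked to
the outcome-phase onsets.  An ordinary least squares regression at every
epoch time point yields a beta time course per regressor per participant.
Group comparison uses one scalar per participant: the peak latency of the
group-mean time course (computed leaving that participant out, within a
6-12 s window) aligns a canonical gamma-density HRF, which is then projected
onto the left-out participant's own beta series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .learners import REWARD_TYPE_PE_CODES, LearnerTrace

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import BehavioralSession, BoldSeries

__all__ = [
    "HRFSpec", "EpochMatrix", "TimecourseResult", "canonical_hrf",
    "trial_regressor", "build_fglm_design", "extract_epochs",
    "timepoint_regression", "loo_hrf_summary", "roi_panel_stats",
    "FGLM_COLUMNS",
]


@dataclass(frozen=True)
class HRFSpec:
    """Canonical hemodynamic response: gamma density, shape 7^2/3^2, rate 7/3^2.

    The density's mode -- the HRF peak -- falls at (shape-1)/rate = 40/7 s
    (~5.71 s) after an impulse.
    """

    shape: float = 49.0 / 9.0
    rate: float = 7.0 / 9.0
    dt: float = 0.2
    t_max: float = 30.0

    @property
    def peak_time(self) -> float:
        return (self.shape - 1.0) / self.rate


def canonical_hrf(spec: HRFSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample the gamma-density HRF on [0, t_max]; returns (times, kernel)."""
    sp = spec or HRFSpec()
    if sp.dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, sp.t_max + sp.dt / 2, sp.dt)
    return t, stats.gamma.pdf(t, sp.shape, scale=1.0 / sp.rate)


# ---------------------------------------------------------------------------
# per-trial parametric regressors


def trial_regressor(session: "BehavioralSession", trace: LearnerTrace,
                    name: str) -> np.ndarray:
    """Raw (un-normalized) per-trial value of a named parametric regressor."""
    t = np.arange(session.n_trials)
    c, u = session.choice, 1 - session.choice
    lookup = {
        "rpe_chosen": lambda: trace.rpe_chosen,
        "rpe_unchosen": lambda: trace.rpe_unchosen,
        "epe_chosen": lambda: trace.epe_chosen,
        "epe_unchosen": lambda: trace.epe_unchosen,
        "rew_outcome_rel": lambda: (session.reward_outcome[c, t]
                                    - session.reward_outcome[u, t]),
        "eff_outcome_rel": lambda: (session.effort_outcome[c, t]
                                    - session.effort_outcome[u, t]),
        "reward_type_pe": lambda: trace.reward_type_pe,
        "reward_type_chosen": lambda: np.array(
            [REWARD_TYPE_PE_CODES[r] for r in session.reward_type]),
        "prob_chosen": lambda: session.displayed_prob[c, t],
        "rew_outcome_chosen": lambda: session.reward_outcome[c, t],
        "rew_outcome_unchosen": lambda: session.reward_outcome[u, t],
        "eff_outcome_chosen": lambda: session.effort_outcome[c, t],
        "eff_outcome_unchosen": lambda: session.effort_outcome[u, t],
    }
    if name not in lookup:
        raise ValueError(f"unknown regressor '{name}'")
    return np.asarray(lookup[name](), dtype=float)


#: outcome-phase parametric regressor sets
FGLM_COLUMNS: dict[str, tuple[str, ...]] = {
    # ROI-selection design: outcome-phase set with separate chosen/unchosen
    # outcome magnitudes and PEs
    "fGLM1": ("reward_type_chosen", "prob_chosen",
              "rew_outcome_chosen", "rew_outcome_unchosen",
              "eff_outcome_chosen", "eff_outcome_unchosen",
              "rpe_chosen", "rpe_unchosen", "epe_chosen", "epe_unchosen"),
    # PE design: chosen/unchosen PEs, relative outcomes, reward-type PE
    "fGLM2": ("rpe_chosen", "rpe_unchosen", "epe_chosen", "epe_unchosen",
              "rew_outcome_rel", "eff_outcome_rel", "reward_type_pe"),
    # fGLM2 without the outcome confounds
    "fGLM2_reduced": ("rpe_chosen", "rpe_unchosen", "epe_chosen",
                      "epe_unchosen", "reward_type_pe"),
}


def build_fglm_design(session: "BehavioralSession", trace: LearnerTrace,
                      spec: str) -> pd.DataFrame:
    """Z-scored per-trial regressor table for fGLM1 / fGLM2 / fGLM2_reduced."""
    if spec not in FGLM_COLUMNS:
        raise ValueError(f"unknown fGLM spec '{spec}'; "
                         f"expected one of {tuple(FGLM_COLUMNS)}")
    cols = {}
    for name in FGLM_COLUMNS[spec]:
        x = trial_regressor(session, trace, name)
        sd = x.std()
        if sd <= 1e-12:
            warnings.warn(f"{spec}: constant regressor '{name}' dropped")
            continue
        cols[name] = (x - x.mean()) / sd
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# epoching and time-point regression


@dataclass
class EpochMatrix:
    """Trial x time-point BOLD epochs on the upsampled grid."""

    epochs: np.ndarray          # (n_trials_kept, n_timepoints)
    times: np.ndarray           # seconds relative to outcome onset
    trial_index: np.ndarray     # indices of kept trials

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class TimecourseResult:
    """Per-time-point regression weights for one participant."""

    betas: pd.DataFrame         # rows: time points; columns: regressors
    times: np.ndarray
    participant_id: str = ""

    def series(self, regressor: str) -> np.ndarray:
        return self.betas[regressor].to_numpy()


def extract_epochs(bold: "BoldSeries", onsets: np.ndarray | None = None,
                   window_s: float = 20.0, upsample: int = 10) -> EpochMatrix:
    """Z-score the series, upsample by linear interpolation and epoch at onsets."""
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    onsets = bold.onsets if onsets is None else np.asarray(onsets, dtype=float)
    sig = np.asarray(bold.signal, dtype=float)
    sd = sig.std()
    if sd == 0:
        warnings.warn("constant BOLD series; epochs are all zero")
        sig = np.zeros_like(sig)
    else:
        sig = (sig - sig.mean()) / sd
    raw_t = np.arange(len(sig)) * bold.tr_s
    dt = bold.tr_s / upsample
    rel = np.arange(0.0, window_s + dt / 2, dt)
    t_end = raw_t[-1]
    keep, rows = [], []
    for i, o in enumerate(onsets):
        if o < 0 or o + window_s > t_end:
            warnings.warn(f"epoch for trial {i} exceeds series span; dropped")
            continue
        rows.append(np.interp(o + rel, raw_t, sig))
        keep.append(i)
    return EpochMatrix(np.asarray(rows), rel, np.asarray(keep, dtype=int))


def timepoint_regression(epochs: EpochMatrix,
                         design: pd.DataFrame,
                         participant_id: str = "") -> TimecourseResult:
    """OLS of across-trial BOLD values on the design at every epoch time point."""
    X = design.to_numpy(dtype=float)
    if len(epochs.trial_index) != len(design):
        X = X[epochs.trial_index]
    if X.shape[0] != epochs.n_trials:
        raise ValueError("epoch rows and design rows do not match")
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        r = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices_from(r, k=1)
        worst = np.argmax(np.abs(r[iu]))
        i, j = iu[0][worst], iu[1][worst]
        raise ValueError("rank-deficient design; most collinear columns: "
                         f"'{design.columns[i]}' and '{design.columns[j]}'")
    beta, *_ = np.linalg.lstsq(Xi, epochs.epochs, rcond=None)
    betas = pd.DataFrame(beta[1:].T, columns=list(design.columns))
    return TimecourseResult(betas, epochs.times, participant_id)


# ---------------------------------------------------------------------------
# leave-one-out HRF alignment and group statistics


def _shifted_kernel(times: np.ndarray, peak_at: float, hrf: HRFSpec) -> np.ndarray:
    """Gamma HRF evaluated so that its peak lands at ``peak_at`` seconds."""
    shift = peak_at - hrf.peak_time
    t = times - shift
    k = np.zeros_like(times)
    pos = t > 0
    k[pos] = stats.gamma.pdf(t[pos], hrf.shape, scale=1.0 / hrf.rate)
    return k


def loo_hrf_summary(timecourses: list[TimecourseResult], regressor: str,
                    groups: list[str] | None = None,
                    hrf: HRFSpec | None = None,
                    peak_window_s: tuple[float, float] = (6.0, 12.0)) -> np.ndarray:
    """One scalar per participant by leave-one-out HRF peak alignment.

    For each participant the remaining same-group participants' beta time
    courses are averaged; the absolute peak (strongest peak or trough) of that
    mean within ``peak_window_s`` sets the HRF alignment; the scalar is the sum
    over time points of the aligned kernel times the left-out participant's
    own beta series.  Ties in the peak search break toward the earliest time.
    """
    hrf = hrf or HRFSpec()
    n = len(timecourses)
    if groups is None:
        groups = ["all"] * n
    groups = list(groups)
    for g in set(groups):
        if groups.count(g) < 3:
            raise ValueError(f"need >= 3 participants per group; '{g}' has "
                             f"{groups.count(g)}")
    times = timecourses[0].times
    lo, hi = peak_window_s
    win = (times >= lo) & (times <= hi)
    if not win.any() or hi > times[-1]:
        raise ValueError(f"peak window {peak_window_s} not covered by the "
                         f"epoch window [0, {times[-1]:.1f}] s")
    series = np.vstack([tc.series(regressor) for tc in timecourses])
    scalars = np.empty(n)
    for i in range(n):
        mask = np.array([j != i and groups[j] == groups[i] for j in range(n)])
        mean_series = series[mask].mean(axis=0)
        widx = np.flatnonzero(win)
        peak_idx = widx[int(np.argmax(np.abs(mean_series[widx])))]
        kernel = _shifted_kernel(times, float(times[peak_idx]), hrf)
        scalars[i] = float(np.sum(kernel * series[i]))
    return scalars


def roi_panel_stats(scalars: pd.DataFrame, groups: list[str],
                    alpha: float = 0.05) -> dict:
    """Mixed group x ROI ANOVA plus per-ROI two-sample t tests.

    ``scalars`` is a participants x ROIs table.  The Bonferroni-adjusted
    per-ROI threshold alpha / n_rois is reported alongside raw p values.
    """
    from .behavior import group_contrast

    if scalars.isna().any().any():
        raise ValueError("missing cells in the participant x ROI table")
    rois = list(scalars.columns)
    out = {"anova": group_contrast(scalars, groups, design="mixed_anova"),
           "bonferroni_threshold": alpha / len(rois),
           "per_roi": {}}
    for roi in rois:
        out["per_roi"][roi] = {
            "ttest": group_contrast(scalars[roi].to_numpy(), groups, "ttest"),
            "welch": group_contrast(scalars[roi].to_numpy(), groups,
                                    "welch_ttest"),
        }
    return out
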