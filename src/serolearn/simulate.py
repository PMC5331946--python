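"""Synthetic cohorts: softmax agents, effort exertion, and ROI BOLD series.

Agents learn the drifting reward and effort magnitudes of both options with a
delta rule, combine them with the displayed reward probability through the
additive utility heuristic, and choose by softmax.  Two group-specific
"interference" attenuation parameters degrade the reward-dimension update on
trials where the reward was only hypothetical (``eta_hypo``) or where the
concurrent relative effort prediction error was unusually large (``eta_epe``).
With both set to zero the generative process is exactly the shared/separate
learning-rate additive softmax model that the fitting module estimates.

ROI BOLD series are built by weighting an impulse train at outcome-phase
onsets with planted (z-scored) trial regressors, convolving with the canonical
gamma HRF and adding AR(1) Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .learners import (
    REWARD_TYPE_PE_CODES,
    BayesHyperParams,
    LearnerTrace,
    run_bayes_learner,
)
from .schedule import (
    ScheduleConfig,
    TaskSchedule,
    TrialTiming,
    generate_schedule,
    generate_timing,
)

__all__ = [
    "GenerativeAgentParams", "ExertionCoefficients", "BehavioralSession",
    "BoldSeries", "GroupConfig", "CohortConfig", "Cohort",
    "simulate_agent", "simulate_effort_exertion", "simulate_roi_bold",
    "simulate_cohort",
]

#: minimum number of preceding trials before the relative-EPE interference
#: trigger can fire (the running top-quartile threshold needs some history)
_EPE_TRIGGER_BURNIN = 8


@dataclass(frozen=True)
class GenerativeAgentParams:
    """Generative parameters of one softmax agent.

    Learning-rate defaults echo the fitted group values reported for this task
    (reward ~0.3-0.4, effort ~0.4-0.5).  ``eta_hypo``/``eta_epe`` attenuate the
    reward-dimension update by (1 - eta) on trials where the reward was
    hypothetical, or where the signed relative (chosen minus unchosen) effort
    PE fell in the top quartile of its running distribution (surprisingly
    high effort).  ``stay_bonus_real`` is a utility bonus for repeating the
    previous choice after a real reward, reproducing the documented
    stay-after-real-reward bias.
    """

    alpha_reward: float = 0.35
    alpha_effort: float = 0.45
    beta: float = 12.0
    gamma: float = 1.5
    lam: float = 1.0
    eta_hypo: float = 0.0
    eta_epe: float = 0.0
    stay_bonus_real: float = 0.05
    interference_mode: str = "update"  # "update" or "use"

    def __post_init__(self):
        for name in ("alpha_reward", "alpha_effort", "eta_hypo", "eta_epe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta", "gamma", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interference_mode not in ("update", "use"):
            raise ValueError("interference_mode must be 'update' or 'use'")


@dataclass(frozen=True)
class ExertionCoefficients:
    """Linear model of the clicking rate (clicks/second) in the effort phase."""

    base: float = 4.0
    chosen_reward: float = 1.0
    irrelevant_reward: float = 0.5
    noise_sd: float = 0.5


@dataclass
class BehavioralSession:
    """One agent's (or participant's) observed trial sequence."""

    schedule: TaskSchedule
    choice: np.ndarray                 # option index 0/1 per trial
    reward_type: list[str]             # "real" | "hypothetical" per trial
    reward_outcome: np.ndarray         # (2, n_trials): scheduled magnitudes
    effort_outcome: np.ndarray
    clicking_rate: np.ndarray
    timing: list[TrialTiming]
    group_label: str = ""
    participant_id: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.choice)

    @property
    def displayed_prob(self) -> np.ndarray:
        return self.schedule.displayed_prob

    @property
    def outcome_onsets(self) -> np.ndarray:
        return np.array([tt.outcome_onset_s for tt in self.timing])

    def to_frame(self) -> pd.DataFrame:
        df = self.schedule.to_frame()
        df["choice"] = self.choice + 1
        df["reward_type"] = self.reward_type
        df["clicking_rate"] = self.clicking_rate
        df["outcome_onset_s"] = self.outcome_onsets
        return df


@dataclass
class BoldSeries:
    """Synthetic ROI BOLD series with its generative bookkeeping."""

    tr_s: float
    signal: np.ndarray
    onsets: np.ndarray
    planted_betas: dict[str, float]
    noise_sd: float
    ar1_rho: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.signal)) * self.tr_s


def _softmax_p0(u0: float, u1: float, beta: float) -> float:
    z = beta * (u0 - u1)
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


def simulate_agent(schedule: TaskSchedule, params: GenerativeAgentParams,
                   rng: np.random.Generator) -> BehavioralSession:
    """Simulate one agent's choices, reward types and outcomes on a schedule.

    Per trial: additive utilities are computed from the agent's internal
    delta-rule predictions (plus the stay bonus after a real reward), a choice
    is drawn by softmax, the reward type is drawn from the chosen option's
    displayed probability, both options' outcomes are revealed, and both
    options' predictions are updated -- with the reward-dimension learning rate
    attenuated on interference trials.
    """
    n = schedule.n_trials
    p = schedule.displayed_prob
    k = 1.0 + params.gamma + params.lam
    # learning track (intact) and decision track; they coincide in
    # "update" mode, where interference attenuates the stored update itself
    pr = np.array([0.5, 0.5])       # decision-track reward predictions
    pr_learn = np.array([0.5, 0.5])
    pe_ = np.array([0.5, 0.5])      # effort predictions (never attenuated)
    choice = np.empty(n, dtype=int)
    reward_type: list[str] = []
    rel_epe_hist: list[float] = []
    prev_choice = -1
    prev_real = False
    for t in range(n):
        u = (p[:, t] + params.gamma * pr - params.lam * pe_) / k
        if prev_real and prev_choice >= 0:
            u[prev_choice] += params.stay_bonus_real
        c = 0 if rng.random() < _softmax_p0(u[0], u[1], params.beta) else 1
        choice[t] = c
        rt_real = rng.random() < p[c, t]
        reward_type.append("real" if rt_real else "hypothetical")
        # prediction errors (pre-update), both options visible
        rpe = schedule.reward_mag[:, t] - pr_learn
        epe = schedule.effort_mag[:, t] - pe_
        rel_epe = epe[c] - epe[1 - c]
        # trigger on surprisingly high (unfavorable) relative effort: top
        # quartile of the running signed rel-EPE distribution.  A symmetric
        # |rel EPE| trigger would be invisible to the linear RPE x EPE
        # interaction that quantifies this interference.
        epe_trigger = False
        if len(rel_epe_hist) >= _EPE_TRIGGER_BURNIN:
            thresh = float(np.quantile(rel_epe_hist, 0.75))
            epe_trigger = rel_epe > thresh
        rel_epe_hist.append(rel_epe)
        atten = 1.0
        if not rt_real:
            atten *= 1.0 - params.eta_hypo
        if epe_trigger:
            atten *= 1.0 - params.eta_epe
        alpha_r_dec = params.alpha_reward * atten
        if params.interference_mode == "update":
            pr = pr + alpha_r_dec * (schedule.reward_mag[:, t] - pr)
            pr_learn = pr.copy()
        else:  # "use": intact learning, attenuated incorporation into decisions
            pr_learn = pr_learn + params.alpha_reward * rpe
            pr = pr + alpha_r_dec * (schedule.reward_mag[:, t] - pr)
        pe_ = pe_ + params.alpha_effort * epe
        prev_choice = c
        prev_real = rt_real
    timing = generate_timing(n, schedule.config.timing, rng)
    session = BehavioralSession(
        schedule=schedule, choice=choice, reward_type=reward_type,
        reward_outcome=schedule.reward_mag.copy(),
        effort_outcome=schedule.effort_mag.copy(),
        clicking_rate=np.zeros(n), timing=timing,
    )
    session.clicking_rate = simulate_effort_exertion(session, ExertionCoefficients(), rng)
    return session


def simulate_effort_exertion(session: BehavioralSession,
                             coef: ExertionCoefficients,
                             rng: np.random.Generator) -> np.ndarray:
    """Clicking rate driven by the chosen reward and irrelevant reward information.

    rate = base + c1 * chosen reward outcome
                + c2 * mean(unchosen reward outcome, reward-type code)
                + Gaussian noise, truncated at zero.
    """
    if coef.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(session.n_trials)
    chosen_rew = session.reward_outcome[session.choice, t]
    unchosen_rew = session.reward_outcome[1 - session.choice, t]
    rt_code = np.array([REWARD_TYPE_PE_CODES[r] for r in session.reward_type])
    irrelevant = 0.5 * (unchosen_rew + rt_code)
    rate = (coef.base + coef.chosen_reward * chosen_rew
            + coef.irrelevant_reward * irrelevant
            + rng.normal(0.0, coef.noise_sd, size=session.n_trials))
    return np.maximum(rate, 0.0)


def simulate_roi_bold(session: BehavioralSession, trace: LearnerTrace,
                      planted: dict[str, float], hrf=None,
                      noise: tuple[float, float] = (1.0, 0.3),
                      rng: np.random.Generator | None = None,
                      tr_s: float = 2.0) -> BoldSeries:
    """Synthesize an ROI BOLD series with planted outcome-phase effects.

    Each trial contributes an impulse at its outcome onset with amplitude
    sum_j beta_j * z(regressor_j); the train is convolved with the canonical
    gamma HRF (peak-normalized, so a planted beta is the peak response
    amplitude per SD of the regressor, in the same units as ``noise_sd``),
    sampled at ``tr_s``, and AR(1) noise is added.
    """
    from .bold import HRFSpec, canonical_hrf, trial_regressor

    if rng is None:
        rng = np.random.default_rng()
    noise_sd, rho = noise
    if not -1.0 < rho < 1.0:
        raise ValueError("ar1_rho must be in (-1, 1)")
    onsets = session.outcome_onsets
    amp = np.zeros(session.n_trials)
    for name, beta in planted.items():
        x = trial_regressor(session, trace, name)
        sd = x.std()
        if sd <= 1e-12:
            warnings.warn(f"planted regressor '{name}' is constant; skipped")
            continue
        amp += beta * (x - x.mean()) / sd
    dt = tr_s / 10.0
    t_end = onsets[-1] + 30.0
    n_fine = int(np.ceil(t_end / dt)) + 1
    train = np.zeros(n_fine)
    for o, a in zip(onsets, amp):
        train[int(round(o / dt))] += a
    spec = hrf or HRFSpec(dt=dt)
    if spec.dt != dt:
        spec = replace(spec, dt=dt)
    _, kernel = canonical_hrf(spec)
    fine = np.convolve(train, kernel / kernel.max())[:n_fine]
    n_tr = int(np.floor(t_end / tr_s)) + 1
    signal = fine[(np.arange(n_tr) * round(tr_s / dt)).astype(int)]
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=n_tr)
        ar = np.empty(n_tr)
        ar[0] = eps[0] / np.sqrt(1.0 - rho ** 2)
        for i in range(1, n_tr):
            ar[i] = rho * ar[i - 1] + eps[i]
        signal = signal + ar
    return BoldSeries(tr_s=tr_s, signal=signal, onsets=onsets,
                      planted_betas=dict(planted), noise_sd=noise_sd,
                      ar1_rho=rho)


@dataclass(frozen=True)
class GroupConfig:
    """One treatment group: size, generative parameter means and SDs.

    Defaults define the two study-like groups via :func:`default_groups`:
    an "ssri-like" group (n=15, reward learning rate 0.31, no interference)
    and a "placebo-like" group (n=14, reward learning rate 0.38, strong
    interference eta = 0.9 on both triggers).
    """

    name: str
    n: int
    param_means: GenerativeAgentParams
    param_sds: dict[str, float] = field(default_factory=lambda: {
        "alpha_reward": 0.08, "alpha_effort": 0.08, "beta": 2.0,
        "gamma": 0.2, "lam": 0.15,
    })
    planted_bold: dict[str, float] = field(default_factory=dict)


def default_groups() -> list[GroupConfig]:
    return [
        GroupConfig(
            name="ssri-like", n=15,
            param_means=GenerativeAgentParams(
                alpha_reward=0.31, alpha_effort=0.41,
                eta_hypo=0.0, eta_epe=0.0),
            planted_bold={"rpe_chosen": 1.0},
        ),
        GroupConfig(
            name="placebo-like", n=14,
            param_means=GenerativeAgentParams(
                alpha_reward=0.38, alpha_effort=0.47,
                eta_hypo=0.9, eta_epe=0.9),
            planted_bold={"rpe_chosen": 0.0},
        ),
    ]


@dataclass
class CohortConfig:
    groups: list[GroupConfig] = field(default_factory=default_groups)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    bayes_hyper: BayesHyperParams = field(default_factory=BayesHyperParams)
    simulate_bold: bool = False
    bold_noise: tuple[float, float] = (1.0, 0.3)
    bold_tr_s: float = 2.0


@dataclass
class Cohort:
    sessions: list[BehavioralSession]
    traces: list[LearnerTrace]
    groups: list[str]
    params: list[GenerativeAgentParams]
    bold: list[BoldSeries] | None
    seed: int

    @property
    def n(self) -> int:
        return len(self.sessions)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.groups])


_BOUNDED01 = ("alpha_reward", "alpha_effort", "eta_hypo", "eta_epe")


def _sample_params(means: GenerativeAgentParams, sds: dict[str, float],
                   rng: np.random.Generator) -> GenerativeAgentParams:
    updates = {}
    for name, sd in sds.items():
        mu = getattr(means, name)
        v = rng.normal(mu, sd)
        if name in _BOUNDED01:
            v = float(np.clip(v, 0.01, 0.99))
        else:
            v = float(max(v, 1e-3))
        updates[name] = v
    return replace(means, **updates)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate a full cohort: schedules, agents, Bayesian traces, optional BOLD."""
    cfg = config or CohortConfig()
    sessions: list[BehavioralSession] = []
    traces: list[LearnerTrace] = []
    groups: list[str] = []
    params_out: list[GenerativeAgentParams] = []
    bold: list[BoldSeries] = []
    pid = 0
    for g in cfg.groups:
        for _ in range(g.n):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(1, pid))
            s_sched, s_agent, s_bold = ss.spawn(3)
            sched_seed = int(s_sched.generate_state(1)[0] % (2 ** 31))
            schedule = generate_schedule(cfg.schedule, seed=sched_seed)
            agent_rng = np.random.Generator(np.random.PCG64(s_agent))
            params = _sample_params(g.param_means, g.param_sds, agent_rng)
            session = simulate_agent(schedule, params, agent_rng)
            session.group_label = g.name
            session.participant_id = f"p{pid:03d}"
            trace = run_bayes_learner(session, cfg.bayes_hyper)
            sessions.append(session)
            traces.append(trace)
            groups.append(g.name)
            params_out.append(params)
            if cfg.simulate_bold:
                bold_rng = np.random.Generator(np.random.PCG64(s_bold))
                bold.append(simulate_roi_bold(
                    session, trace, g.planted_bold, noise=cfg.bold_noise,
                    rng=bold_rng, tr_s=cfg.bold_tr_s))
            pid += 1
    return Cohort(sessions, traces, groups, params_out,
                  bold if cfg.simulate_bold else None, seed)
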