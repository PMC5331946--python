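"""Task schedules: drifting reward/effort magnitudes, displayed probabilities, timing.

A session consists of 120 trials on which two options each carry a reward
magnitude and an effort magnitude that drift slowly (reflected Gaussian random
walks), plus a per-trial displayed probability that a chosen option pays a real
(rather than hypothetical) reward.  Schedules are screened so that the task
factors vary independently; a schedule whose raw columns correlate too strongly
is regenerated from an incremented sub-seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleConfig", "TaskSchedule", "TrialTiming", "TimingConfig",
    "generate_magnitude_walk", "generate_schedule", "draw_reward_type",
    "check_decorrelation", "generate_timing",
]

#: displayed-probability cue values; the grid is deliberately narrower than the
#: full [0,1] range because the trial's reward type is drawn from the displayed
#: probability, which structurally correlates the two regressors by
#: sqrt(Var(p) / (Var(p) + E[p(1-p)])) -- 0.34 on this grid.
DEFAULT_PROB_GRID = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75)


class ScheduleGenerationError(RuntimeError):
    """Raised when no schedule passes the decorrelation screen within the attempt cap."""


@dataclass(frozen=True)
class TimingConfig:
    """Phase duration ranges (seconds) for one trial.

    Durations are drawn uniformly from the stated ranges: an initial monitoring
    phase of 1.4-4.5 s, a choice-highlight phase of 2.9-8 s, a chosen-outcome
    display of 1.9-2.1 s and an unchosen-outcome display of 1.9-6.9 s, followed
    by the effort phase (fixed nominal duration here) and an inter-trial
    interval.
    """

    monitoring_s: tuple[float, float] = (1.4, 4.5)
    highlight_s: tuple[float, float] = (2.9, 8.0)
    chosen_outcome_s: tuple[float, float] = (1.9, 2.1)
    unchosen_outcome_s: tuple[float, float] = (1.9, 6.9)
    effort_s: float = 5.0
    iti_s: float = 2.0


@dataclass(frozen=True)
class ScheduleConfig:
    n_trials: int = 120
    drift_sd: float = 0.10
    bounds: tuple[float, float] = (0.05, 0.95)
    prob_grid: tuple[float, ...] = DEFAULT_PROB_GRID
    decorrelation_threshold: float = 0.2
    mean_tolerance: float = 0.05
    max_attempts: int = 50000
    timing: TimingConfig = field(default_factory=TimingConfig)


@dataclass
class TrialTiming:
    monitoring_s: float
    highlight_s: float
    chosen_outcome_s: float
    unchosen_outcome_s: float
    effort_s: float
    iti_s: float
    outcome_onset_s: float

    @property
    def duration_s(self) -> float:
        return (self.monitoring_s + self.highlight_s + self.chosen_outcome_s
                + self.unchosen_outcome_s + self.effort_s + self.iti_s)


@dataclass
class TaskSchedule:
    """Per-trial generative state of the task.

    Arrays are shaped (2, n_trials): row 0 is option 1, row 1 is option 2.
    """

    n_trials: int
    reward_mag: np.ndarray
    effort_mag: np.ndarray
    displayed_prob: np.ndarray
    seed: int
    config: ScheduleConfig = field(default_factory=ScheduleConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(1, self.n_trials + 1),
            "rew_mag_1": self.reward_mag[0], "rew_mag_2": self.reward_mag[1],
            "eff_mag_1": self.effort_mag[0], "eff_mag_2": self.effort_mag[1],
            "prob_1": self.displayed_prob[0], "prob_2": self.displayed_prob[1],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1,
                   config: ScheduleConfig | None = None) -> "TaskSchedule":
        required = ["rew_mag_1", "rew_mag_2", "eff_mag_1", "eff_mag_2",
                    "prob_1", "prob_2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"schedule table is missing columns: {missing}")
        n = len(df)
        return cls(
            n_trials=n,
            reward_mag=np.vstack([df["rew_mag_1"], df["rew_mag_2"]]),
            effort_mag=np.vstack([df["eff_mag_1"], df["eff_mag_2"]]),
            displayed_prob=np.vstack([df["prob_1"], df["prob_2"]]),
            seed=seed, config=config or ScheduleConfig(n_trials=n),
        )


def generate_magnitude_walk(n_trials: int, drift_sd: float,
                            bounds: tuple[float, float],
                            rng: np.random.Generator) -> np.ndarray:
    """Gaussian random walk reflected at ``bounds``; start uniform within bounds.

    Reflection folds each proposed step back into the interval, which keeps the
    walk inside [0, 1] for arbitrary drift while preserving small-step
    behaviour away from the edges.
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid bounds {bounds}: need 0 <= lower < upper <= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if drift_sd < 0:
        raise ValueError("drift_sd must be >= 0")
    start = rng.uniform(lo, hi)
    steps = rng.normal(0.0, drift_sd, size=n_trials - 1)
    width = hi - lo
    free = start - lo + np.concatenate([[0.0], np.cumsum(steps)])
    # folding the unreflected walk implements reflection at both bounds
    z = free % (2 * width)
    return lo + width - np.abs(z - width)


def draw_reward_type(p_real: float, rng: np.random.Generator) -> str:
    """Bernoulli draw of the trial's reward type: 'real' with probability p_real."""
    if not 0.0 <= p_real <= 1.0:
        raise ValueError(f"p_real must be in [0, 1], got {p_real}")
    return "real" if rng.random() < p_real else "hypothetical"


def check_decorrelation(regressor_table: pd.DataFrame | np.ndarray,
                        threshold: float) -> tuple[float, bool]:
    """Maximum absolute pairwise Pearson correlation among regressors.

    Constant regressors are excluded with a warning rather than crashing.
    Returns ``(max_abs_corr, passed)`` with ``passed = max <= threshold``.
    """
    if isinstance(regressor_table, pd.DataFrame):
        names = list(regressor_table.columns)
        X = regressor_table.to_numpy(dtype=float)
    else:
        X = np.asarray(regressor_table, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 2 regressors and 3 trials")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant regressors excluded from correlation check: {dropped}")
        X = X[:, keep]
    if X.shape[1] < 2:
        return 0.0, True
    r = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    max_abs = float(np.max(np.abs(r[iu])))
    return max_abs, max_abs <= threshold


def cohort_mean_correlations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-participant mean of absolute pairwise Pearson correlations.

    Every table must share the same columns.  Returns the mean |r| matrix as a
    DataFrame (diagonal NaN).
    """
    cols = list(tables[0].columns)
    acc = np.zeros((len(cols), len(cols)))
    for tab in tables:
        if list(tab.columns) != cols:
            raise ValueError("all regressor tables must share identical columns")
        r = np.corrcoef(tab.to_numpy(dtype=float), rowvar=False)
        acc += np.abs(r)
    acc /= len(tables)
    np.fill_diagonal(acc, np.nan)
    return pd.DataFrame(acc, index=cols, columns=cols)


def max_mean_abs_correlation(tables: list[pd.DataFrame]) -> float:
    """Maximum over regressor pairs of the across-participant mean |r|."""
    m = cohort_mean_correlations(tables).to_numpy()
    iu = np.triu_indices_from(m, k=1)
    return float(np.nanmax(m[iu]))


def _schedule_screen_table(reward_mag, effort_mag, displayed_prob) -> pd.DataFrame:
    return pd.DataFrame({
        "rew_mag_1": reward_mag[0], "rew_mag_2": reward_mag[1],
        "eff_mag_1": effort_mag[0], "eff_mag_2": effort_mag[1],
        "prob_1": displayed_prob[0], "prob_2": displayed_prob[1],
    })


def generate_schedule(config: ScheduleConfig | None = None,
                      seed: int = 0) -> TaskSchedule:
    """Generate a task schedule passing the decorrelation screen.

    The four magnitude walks (2 options x reward/effort) are constructed
    sequentially: each new walk is redrawn from fresh sub-streams of ``seed``
    until (a) its session mean lies within ``config.mean_tolerance`` of the
    bounds' midpoint (a balanced schedule -- unequal walk means otherwise
    leak into every chosen/unchosen and stay/switch regressor pair) and
    (b) its correlation with every already-accepted walk is at most
    ``config.decorrelation_threshold``.  Sequential rejection is required
    because slowly drifting walks exhibit large spurious correlations, so a
    joint accept/reject over whole schedules has a vanishing acceptance rate.
    Displayed probabilities are i.i.d. draws from the configured grid; a final
    screen over all schedule columns guards the construction.
    """
    cfg = config or ScheduleConfig()
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    prob_stream, _ = ss.spawn(2)
    centre = 0.5 * (cfg.bounds[0] + cfg.bounds[1])
    walks: list[np.ndarray] = []
    best = 1.0
    counter = 0
    for _ in range(4):
        accepted = None
        for _ in range(cfg.max_attempts):
            stream = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=seed, spawn_key=(0, 1, counter))))
            counter += 1
            cand = generate_magnitude_walk(cfg.n_trials, cfg.drift_sd,
                                           cfg.bounds, stream)
            if abs(cand.mean() - centre) > cfg.mean_tolerance:
                continue
            if not walks:
                accepted = cand
                break
            if cand.std() == 0 or cfg.n_trials < 3:
                accepted = cand   # degenerate walks cannot correlate
                break
            worst = max(abs(np.corrcoef(cand, w)[0, 1]) if w.std() > 0 else 0.0
                        for w in walks)
            best = min(best, worst)
            if worst <= cfg.decorrelation_threshold:
                accepted = cand
                break
        if accepted is None:
            raise ScheduleGenerationError(
                f"no walk decorrelated below {cfg.decorrelation_threshold} in "
                f"{cfg.max_attempts} attempts (best achieved max |r| = {best:.3f})")
        walks.append(accepted)
    reward_mag = np.vstack(walks[:2])
    effort_mag = np.vstack(walks[2:])
    rng = np.random.Generator(np.random.PCG64(prob_stream))
    displayed_prob = np.asarray(rng.choice(cfg.prob_grid, size=(2, cfg.n_trials)))
    if cfg.n_trials >= 3:
        tab = _schedule_screen_table(reward_mag, effort_mag, displayed_prob)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            max_abs, ok = check_decorrelation(
                tab, max(cfg.decorrelation_threshold, 0.4))
    else:
        max_abs, ok = 0.0, True
    if not ok:
        if seed < 2 ** 31:
            return generate_schedule(cfg, seed=seed + 2 ** 31)
        raise ScheduleGenerationError(
            f"schedule failed the final screen (max |r| = {max_abs:.3f})")
    return TaskSchedule(cfg.n_trials, reward_mag, effort_mag,
                        displayed_prob, seed=seed, config=cfg)


def generate_timing(n_trials: int, config: TimingConfig,
                    rng: np.random.Generator) -> list[TrialTiming]:
    """Draw per-trial phase durations and absolute outcome-phase onsets."""
    timings: list[TrialTiming] = []
    t0 = 0.0
    for _ in range(n_trials):
        mon = rng.uniform(*config.monitoring_s)
        high = rng.uniform(*config.highlight_s)
        cho = rng.uniform(*config.chosen_outcome_s)
        unc = rng.uniform(*config.unchosen_outcome_s)
        onset = t0 + mon + high
        timings.append(TrialTiming(mon, high, cho, unc, config.effort_s,
                                   config.iti_s, onset))
        t0 += mon + high + cho + unc + config.effort_s + config.iti_s
    return timings


def schedule_config_to_dict(cfg: ScheduleConfig) -> dict:
    return asdict(cfg)
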