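# Methods

`serolearn` simulates and analyses a two-option learning task in which human
participants concurrently learn the slowly drifting reward (money) and effort
magnitudes of both options, while a per-trial on-screen probability cue
determines whether the chosen option's reward is actually paid ("real") or
only displayed ("hypothetical"). The package covers the full analysis chain:
task-schedule construction, agent simulation, delta-rule and Bayesian
learners, softmax choice-model fitting with summed-BIC comparison, stay/switch
logistic regressions (including the interference analyses), effort-exertion
regression, and ROI BOLD time-course analysis with leave-one-out HRF peak
alignment. Everything runs from synthetic cohorts; no participant data are
required.

## Task schedules

Each session is 120 trials. The four magnitude trajectories (2 options x
reward/effort) are Gaussian random walks with per-trial step SD `drift_sd`
(default 0.10 on the normalized [0,1] scale), reflected at [0.05, 0.95].
Reflection is implemented by folding the free walk, which is exactly the
reflected process and keeps every value in bounds for arbitrary drift.

Two acceptance rules shape the schedule, both motivated by the requirement
that all task factors vary independently:

* **Balance** — each walk's session mean must lie within 0.05 of the
  midpoint. Without this, unequal between-option means leak into every
  chosen-vs-unchosen and stay-minus-switch regressor pair (cohort mean |r| up
  to ~0.6).
* **Pairwise decorrelation** — each new walk is redrawn until its correlation
  with every accepted walk is at most 0.2. Slow walks have heavy-tailed
  spurious correlations (two independent 120-trial walks correlate at
  |r| ~ 0.4 on average), so walks are rejected one at a time rather than
  whole schedules (whose joint acceptance rate is effectively zero).

Displayed probabilities are i.i.d. draws from a grid, default
{0.25, 0.35, 0.45, 0.55, 0.65, 0.75}. The grid is deliberately narrower than
[0,1]: the trial's reward type is drawn from the displayed probability of the
chosen option, which structurally correlates the two regressors by
`sqrt(Var(p) / (Var(p) + E[p(1-p)]))` — 0.34 on this grid versus 0.57 on a
{0.1..0.9} grid, which would exceed the decorrelation bound the design is
required to meet.

Trial phase durations are drawn uniformly from the task's stated ranges
(monitoring 1.4–4.5 s, highlight 2.9–8 s, chosen outcome 1.9–2.1 s, unchosen
outcome 1.9–6.9 s), plus a nominal 5 s effort phase and a configurable 2 s
inter-trial interval (both only matter for synthetic BOLD timing).

## Learners

The delta-rule (Rescorla–Wagner) learner updates each option's reward and
effort prediction by `alpha * (outcome - prediction)`. Both options are
updated every trial because both outcomes are displayed. Predictions start at
the uninformative midpoint 0.5.

The Bayesian learner is an independent Kalman filter per option x dimension,
tracking a Gaussian random walk with drift variance matched to the schedule
(`drift_sd**2`) and an observation variance of 0.0375 representing perceptual
noise in reading the magnitude displays (SD ~ 0.19 on the [0,1] scale). These
hyperparameters place the stationary gain at 0.40. The gain matters: the
filter is documented to be near-equivalent to the best-fitting delta rule
(prediction-series correlation > 0.99), so its effective gain must sit in the
range of fitted learning rates; and all behavioral PE regressors are derived
from this filter, so a filter that updates much faster than the agents it
describes cancels — or sign-flips — the behavioral PE weights (we verified
this empirically before fixing the gain). Priors are mean 0.5, variance 0.25.
Prediction errors are outcome minus the pre-update mean; the reward-type PE
is the reward-type code (real = 1, hypothetical = 0) minus the chosen
option's displayed probability.

## Choice models and fitting

Utilities follow the two printed rules on normalized [0,1] inputs:

* additive (heuristic): `U = (p + gamma*r - lambda*e) / (1 + gamma + lambda)`
* multiplicative (normative): `U = (p*r - lambda*e) / (1 + lambda)`

Choice probabilities are softmax with inverse temperature `beta`. The model
family crosses {Bayesian, shared-alpha delta rule, separate-alphas delta
rule} x {additive, multiplicative}; the Bayesian variants carry no
learning-rate parameter. Per participant, the negative log-likelihood is
minimized by multi-start Nelder–Mead simplex on sigmoid-transformed
parameters (bounds alpha in (0,1), beta in (0,1000), gamma/lambda in (0,100));
models are compared by `BIC = 2*NLL + k*ln(n_trials)` summed over
participants, ties resolved by declared model order. The first trial is
included in the likelihood using the initialization values, keeping n equal
across models.

**Regularized fitting (default).** Plain maximum likelihood of this family at
120 trials is degenerate: `alpha -> 0` with very large decision weights
mimics a cumulative-mean chooser, and `alpha -> 1` a one-back chooser, and
either corner can overfit a single session by a few nats while destroying
parameter interpretability (we verified this across generative regimes,
optimizers and parameterizations; at 3000+ trials the degeneracy disappears).
The default fit therefore optimizes a weakly penalized likelihood — Beta(2,2)
on learning rates, lognormal(ln 5, 1.5^2) on beta, lognormal(ln 0.5, 1.5^2)
on the decision weights — which costs the degenerate corners ~20 nats while
perturbing interior estimates negligibly. The reported NLL and BIC are always
the pure likelihood at the optimum; `regularized=False` gives the plain ML
fit. This is the standard remedy for exactly this pathology in behavioral
model fitting.

Even so, single-session learning-rate estimation in this task is
intrinsically noisy: with full feedback and smooth magnitude drift, the
prediction series of all tracking speeds are highly correlated, so the data
carry little information about `alpha`. Recovery quality (see the acceptance
suite) should be read with that in mind.

## Synthetic agents and the interference mechanism

Agents use the additive utility on their internal delta-rule predictions,
plus a small utility bonus (0.05) for repeating the previous choice after a
real reward — reproducing the documented stay-after-real-reward bias. Reward
types are drawn per trial from the chosen option's displayed probability.

Interference is modelled as attenuation of the reward-dimension update by
`(1 - eta)` on triggered trials: `eta_hypo` triggers when the trial's reward
was hypothetical; `eta_epe` triggers when the signed relative (chosen minus
unchosen) effort PE falls in the top quartile of its running distribution
(i.e., surprisingly high effort). The trigger is signed, not absolute: an
attenuation symmetric in the relative EPE is mathematically invisible to the
linear RPE x EPE interaction used to quantify this interference. Effort
learning is never attenuated. With `eta_* = 0` and no stay bonus, the agent
is exactly the shared/separate learning-rate additive softmax model. An
alternative "use" mode (intact learning, attenuated incorporation into
decisions) is exposed for sensitivity analyses; "update" is the default.

**Calibration.** Generative defaults were chosen by a measured sweep so that
the synthetic cohorts reproduce the documented behavioral phenomena: stay/
switch weights in the published pattern (probability ~ +1, learnt reward
~ +1, learnt effort ~ -0.9, previous reward type ~ +0.2, relative RPE
positive and detectable), the decorrelation bounds on the regressor sets
(cohort max mean |r| ~ 0.43 for the outcome-phase set, ~ 0.16–0.22 for the
stay/switch set), and a positive group interference contrast in >= 80% of
replicate cohorts. The resulting defaults are `beta = 12`, `gamma = 1.5`,
`lambda = 1.0` (reward:effort weight ratio ~1.5, as in the fitted group
values), `drift_sd = 0.10`. Group defaults follow the study arms: an
"ssri-like" group (n = 15, reward/effort learning rates 0.31/0.41, no
interference) and a "placebo-like" group (n = 14, learning rates 0.38/0.47,
`eta_hypo = eta_epe = 0.9`). Between-participant SDs are 0.08 on learning
rates, 2.0 on beta, 0.2/0.15 on the decision weights, truncated to their
domains.

A note on detectability: at these (paper-matched) effect sizes the planted
interference yields a per-participant contrast of d ~ 0.3–0.4; a one-sample
significance test at n = 14 then has ~20–60% power, so the interference
checks are framed as sign-consistency of the group contrast plus calibration
of the test under the null, not as near-certain significance.

## Behavioral regressions

Stay/switch designs drop trial 1 (no previous choice) and express option
quantities in the relative stay-minus-switch frame (stay = previous choice).
All columns are z-scored per participant; interaction terms multiply
z-scored factors; conditional columns (e.g., "RPE when reward was real") are
z-scored on their support and zero elsewhere; quartile splits assign exactly
n//4 trials to each extreme, ties broken by trial order. Reward type is
coded +1/-1 in these designs.

One convention matters a great deal: the interference designs (bGLM2–bGLM5)
use the *previous trial's pre-update* predictions together with the previous
trial's PEs, so that the PE columns carry the update itself. With current
(post-update) predictions the PE columns are redundant for a delta-rule
learner and every PE weight collapses to zero. The task-validation design
(bGLM1) uses the current predictions, matching its role of describing the
current decision.

Logistic fits use maximum likelihood (statsmodels) with perfect separation
reported as `converged=False` and coefficients capped at |20|; the effort
regression is OLS on z-scored reward factors. The interference score per
participant is `(b_RPExRewardType - b_RPExEPE)/2` (the second weight is sign
reversed so that positive always means more interference). Group statistics
are one-sample and two-sample t tests (pooled or Welch) and mixed
group x condition ANOVAs (pingouin) with Greenhouse–Geisser correction when
the within factor has more than two levels.

## ROI BOLD time courses

Synthetic ROI series place an impulse at each outcome-phase onset with
amplitude `sum_j beta_j * z(regressor_j)`, convolve with the canonical gamma
HRF (shape 7^2/3^2, rate 7/3^2; peak at 40/7 ~ 5.71 s), and add AR(1)
Gaussian noise (rho = 0.3) at TR = 2 s. The kernel is peak-normalized in the
simulator, so a planted beta is the peak response amplitude per SD of the
regressor in noise-SD units ("1.0 vs 0.0 at noise 1" is a peak SNR of 1).

Analysis: the series is z-scored globally, upsampled tenfold by linear
interpolation, cut into 20 s epochs at the outcome onsets, and an OLS with
intercept is run across trials at every epoch time point, yielding a beta
time course per regressor (7 z-scored regressors for the PE design; 10 for
the ROI-selection design; a reduced PE design omits the outcome confounds).
The group summary is leave-one-out HRF alignment: for each participant, the
same-group mean time course excluding that participant locates the absolute
peak (strongest peak or trough, earliest tie wins) within 6–12 s; the
canonical HRF is shifted so its peak lands there; the scalar is the sum over
time points of the shifted kernel times the participant's own series. Group
comparisons use t tests per ROI and a mixed group x ROI ANOVA, with the
Bonferroni threshold alpha/n_ROIs reported alongside raw p values.

## Problem sizes and reproducibility

The test-suite studies use the cohort sizes of the study design (15 + 14) and
120-trial sessions; power studies use 100 replicate cohorts; model recovery
uses 20 cohorts of 8 agents fitted with 5 simplex starts — sizes chosen to
make each check statistically meaningful at desk scale. Every random draw
descends from an explicit integer seed via independent sub-streams
(`numpy.random.SeedSequence` spawning), so schedules, cohorts and the full
pipeline are bit-reproducible from (config, seed).

## Known limitations

* The synthetic agents are ideal delta-rule learners with softmax noise; real
  participants show sequential biases, lapses and drifting attention that the
  generator does not emulate. Passing recovery/power checks therefore bounds
  what the pipeline can do on clean data, not what it will achieve on human
  data.
* Learning rates are weakly identified per session (see above); group-level
  conclusions are robust, individual `alpha` estimates are not.
* BOLD synthesis is an impulse-train + HRF + AR(1) abstraction of one ROI; it
  does not model drift, motion, physiological noise or spatial structure, and
  whole-brain analyses are out of scope by design (the ROI series is the
  input).
* The Bayesian learner uses fixed hyperparameters (no volatility tracking);
  it is a stand-in for the original model whose full specification is not
  publicly stated.
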