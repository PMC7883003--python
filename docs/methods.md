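# Methods

This note documents the models implemented in `counterbart`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish.

## The task and its closed forms

The advance-bid Balloon Analogue Risk Task (BART) used here works on
integer state: a per-pump point value drawn uniformly from 1..100, a bid
of 1..12 pumps committed before the outcome, and a hidden safe limit
drawn from the **discrete** uniform distribution on the 13 integers
0..12, with a bust exactly when the bid strictly exceeds the limit.
Under these rules

- P(bank | n) = (13 − n) / 13,
- expected banked pumps f(n) = n (13 − n) / 13,
- f is maximized at the tie n ∈ {6, 7} with f = 42/13 ≈ 3.23, and
- a cohort with mean bid 4.97 banks (13 − 4.97)/13 ≈ 0.618 ≈ 62% of
  trials, because the bank probability is linear in the bid.

The discrete form is a deliberate modeling choice: a continuous uniform
limit would produce a unique optimum at 6 and a different bank rate, so
the discrete form is the one consistent with the tied 6-or-7 optimum and
the ~.62 integrated bank rate. It remains an inference from observable
consequences rather than a documented implementation detail of the
original software, and it is isolated in one module (`task.py`) should a
user want to vary it.

Information costs are modeled as: a 5-point deduction from the
cumulative banked score (money; negative balances are permitted, since
nothing in the task forbids them), a Bernoulli success gate with
configurable probability standing in for the key-press effort threshold
(defaults 0.88 and 0.92, the complements of the observed 12% and 8%
"try harder" rates), or a recorded waiting time in seconds (time).

## Agent simulation of the information's (non-)instrumentality

Three agent families play the task for 60 trials:

- information seekers: n′ = n + (limit − n)·α + e,
- outcome observers: n′ = n + (12 − n)·α + e after a bank,
  n′ = n + (0 − n)·α + e after a bust,
- baseline random walk: n′ = n + e,

with α ∈ (0, 1), e ~ N(0, σ²), and σ ∈ {0, 1, 2, 3}. Raw updates are
rounded to the nearest integer and clamped to 1..12 (the task accepts
only integer bids). Seekers apply the same signed rule after busts
(limit − n < 0), reading "adjust in proportion to the difference seen"
as bidirectional. Per-trial points are the banked pumps, value-free, so
all means lie in [0, 12]. α is searched on a deterministic dense grid
(step 0.02 over the open unit interval) rather than sampled randomly,
for reproducibility; a cohort is 10,000 agents per type per condition.

**Maximum point gain** is a strategy's best grid mean minus the baseline
cohort mean at the same σ; the headline **benefit** is the seeker
maximum gain minus the observer maximum gain, which is algebraically
independent of the baseline. Common random numbers (shared limit, noise,
and start streams within a σ level) couple all strategies and grid
points, and the benefit's Monte-Carlo SE is computed from the paired
per-agent differences at the two optimal α values.

**Initial bids.** Agents start at the optimal bid of 6. With dispersed
starting bids, a 60-trial run is dominated by the initial-condition
transient: the observers' pull toward the extreme limits mean-reverts at
twice the seekers' rate (linearizing the expected update around the
fixed point gives rates ≈ 2α versus α), so the comparison would largely
measure recovery from arbitrary starts rather than the informational
value of seeing the limit. Starting at the optimum isolates what the
sweep is meant to quantify — how well each feedback rule *maintains*
good play as volatility grows — and is the configuration under which the
benefit's sign structure (≈ 0 at σ = 0, around −0.06 to −0.08 at higher
σ) emerges. `initial="uniform"` restores dispersed starts. A side
effect worth knowing: with the optimal start, the maximum point gain of
each strategy is ≈ 0 at σ = 0 (there is nothing to improve on) and is
not monotone in σ.

At σ = 0 the integer rounding has a visible consequence: updates smaller
than half a pump round to zero, so for α < 1/12 an agent at the optimum
never moves, and both adaptive strategies attain the optimal static mean
exactly; their benefit at σ = 0 is exactly zero.

## Synthetic cohorts

The generator produces tidy trial tables with the statistical structure
the analyses assume, so the whole chain is testable without any data
download. Per participant: a pump policy mean ~ N(4.97, 1.26²) (the
between-participant SD is the integrated SE 0.23 scaled by √30, since
only SEs are printed), integer bids ~ round N(policy, 1.5²) clamped to
1..12; an information-seeking propensity on the logit scale around the
condition base rate (defaults .67, .18, .56, .46, .44; participant logit
SD 1.0); uncorrelated random effects (SD 0.1 each, a calibration choice
— no variance components are printed) for the intercept and each slope.

Emotion change (standardized units) is generated as

  y = β_IS·s + β_PV·pv* + β_MO·mo* + β_IS×PV·s·pv* + β_IS×MO·s·mo*
      + random effects + ε,

where s = ±1 is effect-coded seeking, pv* is the pump value standardized
by the known uniform(1..100) moments, and mo* is the missed opportunity
centered at the participant-level constant (12 − policy mean)/2. The
analysis instead centers empirically within participants; the two
codings differ only by participant-level constants, which the random
intercept and slopes absorb, so planted slopes are recovered without
bias. The residual SD is auto-calibrated by a short feedback-free Monte
Carlo so analyzed-row variance ≈ 1, keeping planted coefficients on the
standardized-outcome scale the analyses report. Ratings are stored on
the task's −200..200 scale (60 VAS points per standardized unit,
clipped; clipping touches well under 1% of draws). Default planted
coefficients are the interaction-model values (−0.173, 0.000, −0.163,
−0.125, −0.144); recovery runs plant whichever set they test.

The felt emotion feeds back on the next bid by γ pumps per SD (default
−0.089: feel worse → pump more), closing the loop the path model
estimates. Rounding and clamping of bids attenuate the recovered
feedback coefficient relative to γ, so path-stage tests assert its sign
and significance, not its value.

The one-shot replication generator emulates the 361-person design: ten
practice trials without an information option, one critical trial at a
fixed value of 20 pence per pump, information offered only to bankers at
a 30-s wait, seek rate 0.71, and a change score carrying the planted
seek and missed-opportunity effects. With the default policy ≈ 60% of
participants bank, matching the observed 59.83%.

What the generator does **not** emulate: the psychometrics of the
outcome rating (cosmetic values only), response times, recruitment and
bonus bookkeeping, serial dependence in seeking, or any guarantee that
the original data-generating process had this form. Passing recovery
tests shows the estimators are correct for data with the assumed
structure; it is not evidence about the human data.

## Mixed-model stage

Per experiment, standardized emotion change on retained bank trials
(practice and try-harder rows excluded; standardization is computed over
the rows entering the model) is regressed on effect-coded seeking,
sample-standardized-then-within-centered pump value, and within-centered
missed opportunity, with a participant random intercept and uncorrelated
random slopes for every trial-level predictor (variance components,
REML). Step 1 fits main effects; Step 2 adds the two interactions with
seeking. Inference is Wald z throughout (matching the z-based reporting
the meta layer consumes); no Satterthwaite correction is applied.

A fit is flagged singular when any variance component collapses to ~0
(tolerance 1e−6). By default the model is then refit after dropping
random slopes in a fixed order — interaction slopes first, then pump
value, then missed opportunity, then seeking, never the intercept — and
the flag records that a reduction happened. A fit whose fixed-effect
covariance is unusable (non-finite or non-positive diagonal) always
walks the same chain regardless of the refit flag.

Simple slopes at seeking = ±1 are b_main + s·b_interaction with the
variance quadratic form from the fixed-effect covariance. The one-shot
replication is analyzed by OLS (seeking × mean-centered missed
opportunity) with t inference, and the group contrast by Welch's t with
Welch–Satterthwaite df and a pooled-SD Cohen's d.

A robustness variant replacing missed opportunity with the number of
pumps is deliberately not exposed as a separate operation; the model
frame is a plain DataFrame and the substitution is a one-line edit for
users who want it.

## Meta-analytic stage

Per-experiment coefficients (b, SE) are pooled under b_k ~ N(μ, se_k² +
τ²). τ² defaults to DerSimonian–Laird (closed form, deterministic);
an iterative REML estimator is available because reference
implementations differ in their default — for the k = 5, near-homogeneous
structures this package targets, the pooled estimates are insensitive to
the choice. CIs are normal-theory (no Knapp–Hartung adjustment),
matching z-based reporting. Heterogeneity is summarized by Cochran's Q
and I² = max(0, (Q − df)/Q)·100, with I² > 50% read as substantial. The
implementation is cross-checked in the test suite against R's `metafor`
on a fixed fixture (agreement to 1e−8 for DL).

## Path stage

Bank trials at t are paired with trial t + 1 to form a lagged frame
(behavior adjustment = pumps(t+1) − pumps(t), positive = riskier; next
outcome as 0/1; next points). Three estimating layers, each OLS with a
participant-clustered sandwich covariance (basic form, no small-sample
correction, z inference):

1. emotion ~ seeking + controls (pump value, missed opportunity, and
   their interactions with seeking);
2. adjustment ~ emotion + the same controls, with no direct seeking
   term (the omitted direct path);
3. next outcome ~ adjustment, and next points ~ adjustment.

Layers are estimated equation by equation; simultaneous SEM estimation
and fit indices are out of scope. The three-path mediation is the
product of coefficients with a multivariate delta-method SE under the
independent-layer approximation (a parametric bootstrap agrees within
10% on fixtures). The next-trial outcome is modeled on the
linear-probability scale, where the task mechanics pin the slope of
outcome on next-trial pumps at −1/13 ≈ −0.077; the slope on the
*adjustment* is attenuated relative to that because the adjustment is
negatively correlated with the current bid.

## Problem sizes and numerical choices

- Agent sweep: 10,000 agents × 60 trials per type per σ, α step 0.02;
  paired Monte-Carlo SE of the benefit < 0.005 points per trial.
- Recovery runs: five experiments of 30 participants × 60 trials.
- The CI-coverage check runs 200 replicates of the full
  generate-fit-pool chain at a reduced size (five experiments of 12
  participants × 24 trials, Step 1, no singular refits), the package's
  choice of a replicate cheap enough to repeat 200 times while
  exercising the same estimator.
- Rounding of bids is round-half-to-even (NumPy's `rint`), applied
  before clamping.
- Degenerate inputs raise: empty α grids, α outside (0, 1), single
  clusters, sub-2 study pools, non-positive SEs, empty trial subsets.

## Known limitations

- The agent simulation's printed-value reproduction depends on
  unstated details (α sampling scheme, integerization, initial bids);
  the defaults here reproduce the benefit extremes to within ±0.03
  points per trial but not to the third decimal.
- MixedLM variance components near zero make singular flags common at
  small cohort sizes; the fallback chain keeps fixed effects estimable,
  but random-effect variances themselves are not reliably recoverable
  at the default sizes and are not asserted anywhere.
- The generator's seek propensity is trial-independent given the
  participant; models of trial-level predictors of seeking are out of
  scope.
- Money costs can drive a participant's cumulative score negative;
  the generator permits this and records it, taking no stance on how
  the original task handled it.
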