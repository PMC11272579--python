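# Methods

## The task and its generative process

A session is a sequence of blocks.  Each block has a *net* of size `N` drawn
uniformly on [12, 72] points (rounded to the nearest integer — the net is a
discrete quantity on screen; offers stay continuous) and three goods whose
offers evolve independently across trials:

- trial-1 offers i.i.d. `Normal(6, 1)` points;
- per trial and per good, with probability 0.1 the offer **jumps up** to
  `start + U(3, 9)` and with probability 0.1 **jumps down** to
  `start − U(3, 9)`, where `start` is that good's trial-1 offer; otherwise
  the offer takes a Gaussian step `Normal(0, 0.8)`.  After a jump, the walk
  continues from the new level, but any later jump again references the
  trial-1 offer.  Offers are not clipped and can go negative.

Choosing the good currently in the net adds its offer (floored so the net
never goes below empty); choosing a different good empties the net first.
`accumulated ≥ N` completes the block.  Goal progress is
`accumulated / N` at decision time (pre-choice), and *trials invested* counts
consecutive choices of the current good.  The first trial of a block has no
current good: persist/abandon is undefined there and such trials are
excluded from all choice fitting and from attention analyses.

**Acceptance filter.**  A candidate block is accepted iff a greedy
tree-search agent (100 rollouts) completes its net in strictly more than 3
and strictly fewer than 15 trials; schedules are built by rejection sampling
(at most 10,000 candidates per accepted block).  Completion counts overshoot
as complete.

## Valuation models

For a state with current goal `g`, accumulated `a`, net `N` and offers `o`:

| model | value of goal | value of alternative |
|---|---|---|
| offer-max | `o_g` | `o_j` |
| myopic | `a + o_g` | `o_j` |
| prospective | `o_g / (N − a)` | `o_j / N` |
| tree-search | `−E[trials to fill]` | `−E[trials to fill]` (net forfeited) |

Prospective negative-offer rules: a negative alternative keeps its raw
(negative) offer; a negative goal offer is scored as the proportion of
progress lost, `o_g / a` (0 when the net is empty — nothing can be lost).
On first trials every good is scored as a fresh start.

**Tree-search planner.**  For each candidate good the agent simulates
choosing it now (with the real forfeiture/floor semantics) and *committing*
to it on every later trial while offers evolve under the true generative
statistics; the value is minus the mean number of trials until completion
over `n_rollouts` Monte-Carlo rollouts.  Design choices:

- *Commit-to-candidate rollouts* — no within-rollout switching; the planner
  scores each good as "how fast would this fill the net if I stuck with
  it", which keeps the computation bounded.
- *Jump reference in rollouts* — the offer level at rollout start plays the
  role of the starting offer.
- *Censoring* — rollouts not finished by `max_horizon` contribute
  `max_horizon` trials (bounded pessimism) rather than being dropped.
- Defaults: `n_rollouts = 100`, `max_horizon = 200`.  The 200-trial horizon
  is deliberately conservative; note that censoring at 200 gives the value
  distribution a long left tail (an offer collapse scores −200 next to
  typical values of −5 to −30).  Analyses that regress on the values
  therefore may prefer a tighter horizon; the asymmetry experiment uses 50
  trials (≈3× the longest plausible goal), which bounds leverage without
  changing choice ranking.
- Session horizon: agents do not reason about the end of the session; the
  session simply truncates after a fixed number of choices.

The abandonment value under any model is
`SV = max_j V(alt_j) − V(goal)`.

## Choice model and fitting

Abandonment choices follow a logistic (softmax) rule
`P(abandon) = 1 / (1 + exp(−(β₀ + β₁·SV)))`.  β₁ is the inverse temperature
(choice consistency); the **indifference point** `IP = −β₀/β₁` is the
abandonment value at which switching reaches probability 0.5, in the units
of the model value (trials, for tree-search).  Positive IP = persistence
bias.

`PersistenceLogit.fit()` runs Newton/IRLS with an L2 (ridge) penalty of
10⁻⁴ on both coefficients, convergence tolerance 10⁻⁸, at most 100
iterations.  Fits are flagged and excluded downstream when the outcome is
constant (separation), the predictor is constant (no identifiable slope),
|β| exceeds 50 (quasi-separation), or the iteration fails to converge.
The reference analysis used a random-intercept-and-slope mixed-effects
logistic; here that is deliberately replaced by a **two-stage scheme**:
per-participant maximum likelihood for individual indifference points, and
a pooled fixed-effects fit across the training participants for the
cross-validation step.  A true hierarchical fit is out of scope.

**Model comparison.**  Leave-one-participant-out cross-validation: for each
held-out participant and candidate model, the pooled logistic is fitted on
everyone else and used to predict the held-out trials; accuracy is
`1 − mean|P̂ − y|`.  Accuracy, not likelihood, so all four single-predictor
models are compared on the same footing.

**Parameter recovery.**  Cohorts with known IP and inverse temperature (and
no progress attenuation, so the generative rule is exactly the fitted
model) are simulated at the study's session length (30 participants × 300
trials) and refitted after *recomputing* tree-search values with
independent rollouts — mirroring how a real participant would be treated.
Monte-Carlo noise in the values acts as errors-in-variables on the slope,
so recovery runs the planner at 300 rollouts.  IP recovery is summarised by
Pearson correlation; inverse-temperature recovery by Spearman correlation,
because the parameter is log-normal and its MLE is heavy-tailed (a few
weakly identified fits dominate a product-moment correlation).  A
split-half (even/odd blocks) ICC(A,1) of fitted IPs serves as the
test-retest analogue.

## Synthetic cohort generator

Per participant: persistence bias `ip_bias ~ Normal(2.0, 1.5)` (trials of
tree-search value — clearly positive on average, matching the
over-persistence regime), inverse temperature log-normal with median 0.8
and log-sd 0.4, progress-attenuation slopes `atten_cur ~ Normal(0.2, 0.1)`
clipped to [0, 1] and `atten_alt = atten_cur + max(0, Normal(0.3, 0.1))`
(alternative-value sensitivity fades faster).  Decisions follow

`SV = inv_temp · [(1 − atten_alt·p)·V_alt − (1 − atten_cur·p)·V_goal − ip_bias]`

with `p` the goal progress; abandonment selects the best alternative; first
trials are greedy over tree-search values.  With both attenuations zero
this is exactly the fitted logistic with `β₁ = inv_temp`, `IP = ip_bias`.

**Attention.**  Each trial all three stimuli appear uniformly on the unit
square; reports add isotropic Gaussian noise with s.d.
`max(0.02, 0.15 + slope·trials_invested)` in normalized screen units, where
the slope is `sp_goal_slope ~ −0.010 − 0.004·z` for the current-goal
stimulus and `≈ 0` (sd 0.002) for alternatives.  Reaction times are
log-normal (median 0.9 s, log-sd 0.25) with a −0.08 s shift for the goal
stimulus.  The attention–persistence coupling is a Gaussian copula:
`ip_bias` loads on one latent factor and the goal-error slope on a second,
correlated with Pearson `2·sin(π·ρ_s/6)` so the induced Spearman
correlation is the target (default 0.5).  The Gaussian-report model is an
assumption — no generative model of human spatial report error is implied
by the behavioural findings it emulates.

**Lesion cohorts.**  23 patients on a 20×24×20 voxel grid at a nominal
2.4 mm pitch (desk-scale stand-in for a whole brain).  Each patient gets
one contiguous random-growth lesion of 50–400 voxels (6-connected growth
from a seed voxel); the first `n_roi_seeded = 5` lesions are seeded at the
designated ROI centre so the region is reliably damaged in a subset.
Behaviour: `bias = 2.0 − effect_delta·[lesion overlaps ROI ball] +
Normal(0, noise_sd)`, default `effect_delta = 3`, `noise_sd = 1`;
`effect_delta = 0` gives an exact null cohort.

What the generator does **not** emulate: learning or value updating within
a session, reaction times for the decision task, realistic lesion
aetiology or vascular territories, and any BOLD signal.  Passing tests on
these cohorts show that the analysis chain recovers structure *of the kind
assumed*, not that human data contain it.

## Behavioural statistics

- **Progress effect** — pooled logistic likelihood-ratio test of
  {SV} vs {SV, progress}, deviance difference on χ²(1).
- **Value × progress interactions** — per-participant logistic of abandon
  on {alt value, −goal value, progress, and the two value × progress
  terms}, then cohort-level t-tests.  Both value sources are coded as
  *pressure to abandon* (goal value sign-flipped), so a negative
  interaction means that pressure source loses influence as the net fills.
  The progress main effect must be included: attenuating a value with a
  nonzero mean induces one, and omitting it biases the interactions.  The
  two value predictors are centred and divided by a *common* scale (the
  mean of their two sds) so the paired interaction contrast is zero under
  equal attenuation.  The asymmetry test is the one-sided paired t-test for
  a more negative alternative × progress coefficient.
- **Attention analysis** — per participant and stimulus status: mean error,
  mean RT, and the OLS slope of error on trials invested; cohort-level
  paired t-tests.  The attention bias is mean alternative error minus mean
  goal error (positive = goal advantage).
- **Bias correlation** — Spearman's ρ with a Fisher-transform CI using
  s.e. `1/√(n−3)` (a documented approximation for rank correlations).
- **Performance** — mean trials per completed net (incomplete blocks
  excluded); lower is better.
- **Group tests** — label-permutation tests for differences in means with
  add-one p-values `(b+1)/(n_perm+1)`; one-sample Wilcoxon signed-rank for
  cohort IP > 0 (exact null for n ≤ 25, normal approximation otherwise).

## Lesion mapping

Per voxel with at least `min_overlap = 2` damaged *and* 2 intact patients,
the two-group t-statistic on persistence bias (identical to the regression
t on a binary damage regressor), signed so positive t = damage predicts
*lower* bias.  Untested voxels carry NaN.  Clusters are connected
components of `{t > 2.3}` under 6-connectivity by default (18/26
configurable).  The chance cluster-size distribution comes from shuffling
biases across patients (default 1,000 permutations):

- `null="pooled"` — the minimum significant size is the smallest `s` such
  that at most 5% of all chance clusters (pooled over permutations) reach
  `s`.  This mirrors the published convention but does **not** control
  family-wise error when many small chance clusters occur per map.
- `null="max"` — the smallest `s` whose add-one p-value against the
  per-permutation *maximum* cluster size is ≤ α; this is the standard
  FWER-controlling construction and is what the calibration experiment
  uses.

The ROI split labels a patient damaged iff any lesioned voxel lies within a
Euclidean ball of radius 3 voxels around the ROI centre.  The radius is
specified in voxels to stay unit-safe (3 voxels × 2.4 mm = 7.2 mm).

## Problem sizes used by the validation experiments

Chosen as desk-scale defaults and fixed in `goalpursuit.experiments`:
schedule statistics on 45 accepted blocks of 100 trials (100 rollouts);
recovery on 30 × 300 trials (300-rollout values); identifiability on 10
repeats × 4 generating models × 6 participants × 150 trials (30 rollouts),
with softmax slopes matched to each model's value scale; asymmetry on 20
effect and 15 null cohorts of 24 × 400 trials (60 rollouts, 50-trial
horizon); lesion calibration on 100 null cohorts × 200 permutations and
power on 20 effect cohorts.

## Known limitations

- No hierarchical (mixed-effects) estimation; pooled fixed effects stand in
  for the group-level fit.
- The planner's rollout count, horizon and no-switch rollout policy are
  assumptions; all are configurable.
- The pooled cluster-correction convention is reported for fidelity but is
  anticonservative; use `null="max"` for error control.
- Spearman CIs via the Fisher transform are approximate at small n.
- The synthetic generator's effect sizes and noise levels are package
  choices targeting the qualitative regime (positive mean persistence
  bias, attention coupling ≈ 0.5), not estimates from human data.
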