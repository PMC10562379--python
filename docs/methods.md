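# Methods

This note records the modelling choices behind `membandit`: what is
simulated, how it is fitted and analysed, which conventions were adopted
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Task environment

**Reward walk.** Each deck's payout probability (percent) follows
`π[t+1] = λ π[t] + (1 − λ) θ + ν`, with stickiness λ = 0.6, Gaussian noise
ν of SD 8 percentage points, and reflecting bounds at 5 and 95. The three
target centers θ are {60, 30, 10}, randomly assigned to decks at the start.
Centers rotate at choice trial 10 and every 30 trials thereafter,
continuing through Phase 2; rotation is implemented as a **cyclic
permutation** of the center assignment, which guarantees that the
highest-paying deck changes at every rotation point. To signal that decks
carry over between rooms, λ is raised to 0.95 for the first three trials
of rooms 2–6; an alternative convention that instead pins the best deck to
a 100% payout on those trials is available via
`RewardWalkConfig(room_start_full_payout=True)` but is off by default (the
default follows the procedure description rather than a figure caption).

**Schedule.** Defaults: 180 learning trials in six 30-trial rooms, 120
Phase-2 choice trials, 60 probes (50 old, 10 novel). Probe placement is
pseudorandom under two constraints chosen here (the exact original
constraints being unspecified): no probe occupies the final Phase-2 slot
and no two probes are adjacent, so every probe is followed by a choice
trial that the intrusion regression can use. Old probes are drawn evenly
across rooms (8–9 per room) from each room's **first ten trials** only,
which decouples the probed trial's reward from the room's overall reward
(centers rotate at trial 10).

**Experiment variants.** Variant 1 uses six unique contexts. Variant 2
uses three scene categories × two exemplars; the first three rooms take
one exemplar per category and rooms 4–6 the foils, ordered by the unique
derangement that never repeats a category across the room-3/room-4
boundary. With cyclic rotation this ordering also makes the modal
highest-center deck differ within every category pair ("opposed"
payoffs); `assign_lure_opposed_walks` verifies that property on the
centers and rejects configurations that cannot satisfy it.

Trial indices and decks are 0-based in memory and 1-based in all CSV
files.

## Hybrid choice model

RL values start at 0 and update only for the chosen deck with rate α_RL.
The sampler values a deck by the recency kernel
`α_sample (1 − α_sample)^(t−i)` over that deck's own past outcomes,
**renormalised over the finite history** so the value is a proper
expectation; a deck never chosen has sampler value 0 (matching the RL
cold start), and α_sample = 0 is treated as its uniform-weight limit.
Because the normalised kernel depends only on the gaps between successive
choices of the same deck, the expectation is updated in O(1) per trial; a
brute-force kernel enumeration in the test suite pins the equivalence to
1e−10.

The softmax adds `β_p` to the previous trial's deck (no term on the first
trial, and none after a missing response), `β_sample · V_sample`, and
`β_RL · V_RL`, with max-logit subtraction for stability. Missing-response
trials contribute no likelihood and advance neither learner. Likelihoods
are computed over the learning phase only; the expectation-form sampler is
used both generatively and in fitting, so recovery compares like with
like (a single-draw sampling policy is not used at fit time).

## MAP fitting

Parameters are optimised on an unbounded scale and logistic-mapped to
their intervals inside the objective; priors — Beta(1.1, 1.1) on the two
rates, Normal(0, 10) truncated to [0, 20] on the inverse temperatures and
to [−3, 3] on perseveration — are evaluated on the bounded scale (no
Jacobian term, matching the estimation procedure being reproduced). BFGS
restarts draw starting points uniformly from [−3, 3] per unbounded
coordinate and stop once the incumbent optimum changes by less than 1e−6
for five consecutive runs (cap: 50 restarts). Identical data and seed give
identical fits.

**Exclusion rule.** The procedure excludes choosers whose fitted model is
not significantly better than the fixed chance model (P = 1/3 each
trial). No test statistic is named in the source procedure; a
likelihood-ratio χ² with df = 5 at α = 0.05 is used, re-maximising the
pure likelihood from the MAP solution so the prior does not penalise the
comparison.

## Probe-intrusion regression

One stacked logistic regression per participant (3 deck parts × 120
Phase-2 choice trials = 360 rows, shared coefficients) with columns DI,
DR1–3, EI, ER, EC; coefficients are log relative choice odds. Conventions
adopted where the source is silent: an intercept is included (not counted
among the seven columns); EC for a deck never chosen in the probed room
is 0 (the 0/0 case — zero contributes no evidence); DR lags cross the
phase boundary into late learning trials and are 0 before trial 1; trials
after novel probes carry zero probe regressors; missing-response trials
contribute no rows. A per-deck (unshared) fit is available via
`shared_parts=False`.

The variant-2 gist column is the EC computed over the probed room pooled
with its same-category foil, then **serially orthogonalised** against the
target EC column — plain projection removal, no mean-centering, no
rescaling of the target.

**Separation.** Strongly value-guided or perseverative agents often
quasi-separate the DI/DR columns. The unpenalised maximum-likelihood fit
is attempted first; on separation or non-convergence a weakly
L2-penalised fit (α = 1) is used and flagged. The penalty is applied on
**standardised** columns and mapped back, so low-variance columns (the
orthogonalised gist column especially) are not shrunk disproportionately —
with raw-scale penalisation the target-vs-gist comparison would be
biased toward the higher-variance target column.

Population inference is a two-tailed one-sample t-test of per-participant
coefficients against zero. Note the regression's reward-history controls
are short-horizon (three lags); value signals with longer memory are
absorbed elsewhere, which is a property of the design being reproduced,
not a defect of the implementation.

## MST response model and LDI

The MST generator is a three-state confusion model with one latent
precision parameter p ∈ [0, 1] and fixed guessing rates — the scoring
only ever uses LDI, so any monotone response model suffices:

| condition | P(old) | P(similar) | P(new) |
| --- | --- | --- | --- |
| foil | 0.10 | 0.10 | 0.80 |
| lure | 0.75·(1 − P(sim)) | 0.10 + 0.70·p | 0.25·(1 − P(sim)) |
| repetition | 0.55 + 0.40·p | ½·(1 − P(old)) | ½·(1 − P(old)) |

so the expected LDI = P(similar|lure) − P(similar|foil) = **0.70 · p**,
linear and monotone in precision. Defaults: 128 study items, 192 test
items in equal thirds. LDI is computed over responded trials only.

## Synthetic cohorts

The cohort layer is the stand-in for a lifespan participant sample. Ages
are uniform integers on [18, 77]. A latent memory precision declines
linearly with age (0.95 at 18, slope −0.0085/year, Gaussian noise SD
0.12, clipped to [0.05, 0.98]), consistent with the well-documented
age-related decline in lure discrimination. Generative parameters encode
the qualitative directions the analyses are designed to detect:

* β_sample = 1.5 + 7·precision + N(0, 0.8) — memory precision promotes
  memory sampling;
* β_RL = 9 − 0.08·(age − 18) + N(0, 1) — RL influence declines with age;
* β_p = −0.7 + 0.022·(age − 18) + N(0, 0.3) — perseveration rises with
  age;
* α_RL ~ U(0.2, 0.8), α_sample ~ U(0.3, 0.9).

Probe trials bias the immediately following choice **additively in logit
space** — `b_item·(EI + ER)` for the probed deck, `b_ctx·EC` of the probed
room, and (variant 2) `b_gist·EC` pooled over the category pair — mirroring
the linear form the regression estimates, so the regression stage has a
well-posed recovery target. Cohort defaults: b_item = 0.5, b_ctx = 1.0,
b_gist = 0, probe recognition accuracy 0.9. Four payoff series are
pre-generated per cohort and assigned randomly across agents, mirroring
the original task administration. All ground-truth parameters are
retained for recovery scoring.

What the generator does **not** emulate: reaction times, attrition,
attention lapses or response automation, stimulus-level perceptual
similarity, or any nonlinearity in how probes bias choice. Passing tests
therefore show the pipeline recovers what this generative family encodes,
not that the human effects themselves are reproduced.

## Correlation machinery

Kendall's τ_b (tie-corrected, asymptotic p) measures all parameter
associations; τ maps to a linear-scale R by R = sin(πτ/2); two
correlations from independent samples are compared by Fisher's z on the
mapped R values with SE √(1/(n₁−3) + 1/(n₂−3)); age-controlled
correlations residualise the model-parameter variable on age by OLS (with
intercept) before correlating — residualising both variables is available
via `both=True`. Raw n is reported throughout.

## Problem sizes and numerical choices

The validation suite uses: 1,000 random histories for the sampler oracle
(tolerance 1e−10); 1,000 small vectors for the τ_b oracle (1e−12); 100
agents × 180 trials for parameter recovery; cohorts of 50 agents — one
signal cohort and 40 null cohorts — for regression recovery and
calibration; two 40-agent variant-2 cohorts for the target-vs-gist
dissociation; and a 200-agent lifespan cohort for the headline direction
checks. Softmax uses max-subtraction; the logistic map is clamped away
from exact bounds inside the optimiser so the prior stays finite;
probabilities sum to 1 within 1e−12.

## Known limitations

* β_RL and β_sample are only weakly separable from 180 trials of
  three-armed binary-outcome data: their value signals are collinear, and
  recovery errors anticorrelate. Rank-correlation recovery for the two
  inverse temperatures is ≈ 0.3–0.45 at 180 trials and rises above 0.55
  by ≈ 540 trials with the identical code path, so the limit is
  informational, not computational. Perseveration (τ ≈ 0.8) and the decay
  rates recover better.
* The age-residualised LDI–β_sample association is small by construction
  (precision varies mostly with age), so its estimate at n = 200 is
  positive but noisy.
* The chance-model exclusion test has little to reject when perseveration
  alone distinguishes a chooser from uniform randomness; synthetic
  cohorts with moderate β_p are essentially never excluded.
* Under the null, the intrusion regression's rejection rate is nominal at
  the tested sizes, but its reward-history controls are short-horizon
  (see above), so calibration should be rechecked if the generator is
  given longer-memory confounds.
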