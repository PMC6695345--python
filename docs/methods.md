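# Methods

## The behavioural model

The discrimination phase is modelled as two-alternative instrumental
learning. Each stimulus–response pair carries an associative strength
`V(s, a)`, initialised at 0 (the "no points" reference, so the first
rewarded trial produces a full positive prediction error) and updated only
for the chosen pair:

    V(s, a) ← V(s, a) + rate · (R − V(s, a)),   R ∈ {0, 1}

Rewards are binary; the task's point magnitudes are not modelled. In
fractionated-rate variants `rate = α_rew` on rewarded trials and `α_ext`
otherwise; single-rate variants use one α. Choice follows a softmax over
`β V + τ C`, where `C` is a global previous-response indicator (not
stimulus-specific): it marks whichever response was emitted on the previous
trial, is zero on the first trial, and is cleared by a missed trial. Missed
trials contribute no likelihood and do not update V. The softmax is
log-sum-exp stabilised and does not overflow for β up to 10³.

The model family has seven members: {α, β, τ} (the winning model),
{α_rew, α_ext, β, τ}, {α_rew, α_ext, β}, {α, β}, {α_rew, α_ext, τ},
{α, τ}, and the random baseline (p = 0.5 for both responses, no free
parameters). Whether the unchosen response should also be updated (fictive
updating) is deliberately not implemented: only the chosen pair learns.

## Hierarchy and priors

Per free parameter: one group-level mean per group and one inter-subject SD
shared across the two groups. Group-mean
priors: Beta(1.1, 1.1) for α-type rates, Gamma(shape 4.82, scale 0.88;
mean ≈ 4.24) for β, Normal(0, 1) for τ. SD hyperpriors: Half-Normal(0.17)
for rates and τ, Half-Normal(2) for β. The gamma prior is read as
shape/scale; the interpretation is recorded in fit metadata and
configurable. Subject parameters are group mean plus a normal deviation
*truncated* to the parameter's support (α ∈ [0, 1], β ≥ 0, τ free).
Truncation rather than clipping keeps the generative and inference models
identical — clipping would put point masses on the bounds that no
continuous posterior could represent. The two-system expression weights
w_goal and w_habit reuse β's prior and SD hyperprior, since they play the
same drive-scaling role.

## Posterior sampling

Sampling is by adaptive Metropolis-within-Gibbs with slice-sampled
hyperparameter directions, compiled with numba. Per sweep:

1. single-site random-walk updates of each subject parameter on an
   unconstrained scale (logit for rates, log for β-type, identity for τ);
2. independence proposals per subject parameter drawn from its group
   truncated normal — proposal and prior cancel, so acceptance is the bare
   likelihood ratio, which decorrelates weakly-identified subjects — plus
   full-vector refreshes of a subject's whole parameter point from the
   group conditional, the only move that hops between modes of a
   near-random subject's bimodal (α, β) posterior;
3. a joint per-subject proposal using a covariance estimated adaptively
   during warmup (2.38/√P scaling), which tracks the α–β likelihood ridge;
4. centered group-mean and SD random-walk updates, repeated per a
   kind-specific schedule (learning-rate columns most often);
5. two non-centered (interweaving) directions handled by slice sampling,
   which self-tunes its step: the group translation (a group mean and all
   its subjects shift together, z-scores fixed) and the SD scale direction
   (an SD and all its deviations rescale together, with the (S+1)·log c
   Jacobian). For learning-rate columns an additional "teleport" move
   proposes a new SD and refreshes every deviation from the new
   conditional (prior and proposal terms cancel), jumping the SD across
   its range in one step. Together these break the hyperparameter–subject
   funnel that otherwise dominates the autocorrelation.

Random-walk step sizes adapt toward 0.44 (scalar) / 0.3 (vector)
acceptance in batches of 50 during warmup and are frozen afterwards.
Chains start from distinct seeded overdispersed points. Desk-scale
default: 4 chains × 2,000 iterations with 30% warmup — adaptation settles
well before 600 iterations, and keeping 1,400 draws per chain measurably
reduces split-R-hat noise compared with discarding half. The original
protocol's 8 × 8,000 is available through configuration. An ``effort``
switch selects between the full move schedule ("thorough", needed for
large cohorts) and a lighter one ("fast") that suffices for the
small-cohort fits of model-comparison sweeps. Convergence is monitored by
split-chain R-hat on every group-level, SD, subject-level and
group-difference quantity, gated at < 1.1. The 95% intervals are
highest-density intervals (shortest contiguous window over sorted draws);
pNZ is the posterior mass on the dominant sign of a difference. Sampler
correctness is validated against conjugate closed forms, long-run
agreement checks, and prior-predictive Kolmogorov–Smirnov tests in the
test-suite.

## Marginal likelihoods

Bridge sampling operates on unconstrained coordinates with all prior
normalising constants and transform Jacobians included, so the estimated
normalising constant is the absolute log marginal likelihood. Posterior
draws are split in half: one half moment-matches a multivariate-normal
proposal (mean, covariance, 10⁻¹⁰ diagonal jitter), the other half enters
the Meng–Wong iteration together with an equal number of fresh proposal
draws. The iteration runs to relative tolerance 10⁻¹⁰ (cap 1,000 steps)
around a median-shifted pivot for stability; non-convergence raises with
the iteration trace. The Monte-Carlo error is the independent-draw
approximation Var(f₁)/(N₁ E[f₁]²) + Var(f₂)/(N₂ E[f₂]²) on the log scale;
autocorrelation of the posterior draws is not corrected for, so the
reported error is mildly optimistic. The random baseline's evidence is
computed exactly (n · ln ½). Posterior model probabilities assume equal
model priors and are computed with max-subtraction; Bayes factors between
adjacent ranks are reported in log10, evidences in natural log; ties break
toward the more parsimonious model.

## Two-system model

Goal values Q(s, a) learn toward reward; habit strengths H(s, a) learn
toward 1 on every emission of a to s regardless of reward. One learning
rate α serves both systems — the task cannot dissociate system-specific
rates. Choice drive: `w_goal · Q(s, a) · u(o(s, a)) + w_habit · H(s, a) +
τ C(a)`, with u the binary outcome utility (1 valued, 0 devalued),
switched instantaneously by the block instruction and never itself
learned. In the devaluation phase the go drive for the learned correct
response is compared with a zero no-go baseline through a logistic;
perseveration enters as the difference of go/no-go indicators. Under HLAT
a go response continues to update H toward 1; under NHLAT H is frozen. No
extinction is applied at test (the phase gives no feedback) except
indirectly via HLAT's habit updating. A consequence of the multiplicative
utility gating: a purely goal-directed agent (w_habit = 0) is *indifferent*
to a devalued stimulus (drive 0, P(go) = ½) rather than actively
withholding, so its habit bias converges to about −0.5 — still strongly
negative, and monotonically decreasing in w_goal, while a pure-habit agent's
bias sits at 0. Whether a no-go bias parameter or H decay for unperformed
responses belongs in the model is left open; both are absent here.

When the devaluation phase of a synthetic cohort is generated for agents
whose learning phase came from the single-system model, the two-system
state is built by *replaying* the emitted learning-phase choices through
the two-system updates, so habit strengths reflect the behaviour actually
produced.

## Synthetic cohorts

Defaults encode the study conditions: 55 control and 68 CUD subjects, 96
learning trials (16 per stimulus, maximum run length 3 — the original
ordering scheme is unreported, so the run-length cap is configurable), nine
12-trial devaluation blocks with 2 of 6 outcomes devalued per block (each
outcome devalued exactly 3 times; the per-block count is configurable, and
counterbalancing requires 9 · n_devalued divisible by 6). Group-level
means: α 0.15 vs 0.115 (the reported credible deficit of 0.035 on the CUD
side), β 4.2 in both groups (no credible difference), τ 0.40 vs 0.38
(difference −0.02). Two of these levels are calibrated against published
findings rather than invented, because the study reports no group-level
parameter values. The τ level is set so that model comparison on synthetic
cohorts reproduces the published evidence structure — a decisive
preference for perseveration-bearing models; weaker stickiness makes the
two-parameter model win, contradicting the reported ranking. The α level
is set in the regime where a full-size cohort yields a *credible* negative
group difference, as reported: at higher learning rates the deterministic
task saturates within a few presentations per stimulus and 96 trials carry
almost no information about α, so the reported credible difference could
never emerge. Inter-subject SDs (α 0.06, β 1.5, τ 0.25) sit in the bulk of
the half-normal hyperpriors. Two-system defaults inject a reduced CUD
goal-directed weight (4.2 → 2.8) with equal habit weights, matching the
reported direction of group effects. A configurable miss probability
(default 0) produces missed trials, which all likelihoods skip.

What the generator does *not* emulate: reaction times, IQ and demographic
confounds, drug-use covariates, point magnitudes, fatigue or attention
drift, and any departure of real subjects from the fitted model family.
Passing recovery tests therefore demonstrate internal consistency of the
estimation machinery under the model's own assumptions, not the adequacy
of the model for real behaviour.

## Problem sizes and numerical choices

Recovery and comparison studies in the test-suite run at reduced scale,
chosen as the smallest sizes at which the checks are informative: the
learning-rate recovery uses 3 cohorts of 40 + 40 subjects at 4 × 2,000
iterations; model recovery uses 10 cohorts of 10 + 10 subjects at
3 × 1,000; the convergence benchmark of `scripts/acceptance.py` uses one
20 + 20 cohort at 4 × 2,000. Bridge estimates use at most 4,000 pooled
draws. Degenerate inputs are handled explicitly: constant chains give
R-hat = NaN with a warning; subjects with no usable trials are excluded
with a warning; infeasible devaluation counterbalancing and unknown
test-phase variants raise errors. All entry points take explicit integer
seeds and are bit-reproducible for fixed configuration.

A consequence of the task geometry deserves emphasis. Individual learning
rates are weakly identified by 96 deterministic-reward trials: the
per-subject profile likelihood is steep only below α ≈ 0.1 and nearly
flat above, and α trades off against β along a likelihood ridge. The
group-difference HDI at desk scale is therefore several times wider than
the published full-cohort interval, and the *posterior mean* of the group
difference systematically amplifies the realised cohort difference
(roughly two- to three-fold at 40 + 40 subjects), because the two groups
can settle at different points of the ridge. Long chains reproduce the
same posterior, and a per-subject maximum-likelihood cross-check shows
even larger dispersion, so this is a property of the data regime, not of
the sampler. Recovery studies therefore test HDI *coverage* of the
generating value — which holds — while point-estimate accuracy of the
group difference at desk scale is documented as out of reach; the
corresponding check in the test-suite is expected to fail and says so in
its docstring.

## Known limitations

- The sampler is a random-walk scheme: adequate at the tested sizes, but
  full-protocol runs (8 × 8,000, 123 subjects) take tens of minutes.
- Bridge-sampling errors ignore draw autocorrelation (see above).
- The two-system test-phase parameterisation beyond the committed design
  (no-go bias, H decay, weight bounds) is unconstrained by the available
  description; conclusions about those components are out of reach.
- Stepwise regression inherits the usual caveats of data-driven selection;
  it is provided because it is part of the analysis chain being
  reproduced, with a cycle guard that stops at a revisited model.
- Inter-subject SDs are shared across the two groups (one SD per
  parameter); a group-specific-SD variant is not implemented.
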