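# Methods

`driftlearn` implements and validates a family of trial-level learning
models for two reinforcement-learning task designs — a single-stimulus
estimation task and a two-armed bandit — together with the hierarchical
Bayesian machinery needed to fit them, compare them, and relate their
parameters across tasks.  This note documents the models, the priors
and sampler, the synthetic-data generator, the numerical choices, and
the known limitations.

## Task designs

**Estimation task.** 10 blocks of 15 trials.  On each trial the
participant first reports an estimate of the block's mean outcome and a
certainty rating (0–10), then observes an outcome drawn from
Normal(block mean, SD), with the block mean fixed within a block
(drawn uniformly on [20, 80]) and SD 4 in five blocks and 8 in the
other five (contiguous halves, order counterbalanced).  The task
yields direct trial-level indices of prediction error
(δ̂ₜ = outcomeₜ − estimateₜ) and learning rate
(α̂ₜ = (estimateₜ₊₁ − estimateₜ)/δ̂ₜ).

**Choice task.** 8 blocks of 20 trials.  Two options pay out from
Gaussian distributions (SD 8) whose means differ by 10 or 20 points
(half the blocks each); one mean is 40, 50 or 60 and the other sits
above or below it.  Only the chosen option's outcome is observed.

## Learning models

All four models maintain a per-option expectation *E* (or posterior
mean *μ*) updated after each observed outcome via the prediction error
δ = O − E.

1. **Constant-rate delta rule (RL).** E′ = E + αδ with a single
   learning rate α ∈ [0, 1].
2. **Asymmetric delta rule (RL2).** Separate rates α₊ (δ > 0) and α₋
   (δ < 0).  With α₊ = α₋ it reduces exactly to RL; δ = 0 leaves E
   unchanged under either branch (the positive branch is taken by
   convention).
3. **Kalman filter (KF).** Learning as Bayesian inference under an
   assumed generative model in which the latent mean follows a Gaussian
   random walk with drift variance ση² and outcomes carry noise
   variance σε².  The trial-specific learning rate is the gain
   αₜ = s²/(σε² + s²), where s² is the current prior variance; after
   each outcome the variance contracts to σε²s²/(σε² + s²) and ση² is
   added, so the stored s² is always the next trial's prior.  Only
   variance ratios are identifiable, so σε² ≡ 1 and ση², s₁² (the
   initial prior variance) are estimated relative to it.  ση² is the
   learner's representation of environmental volatility: ση² > 0 in a
   static task means outcomes are over-weighted and the gain asymptotes
   at the positive root of s² − ση²s − ση²σε² = 0 rather than decaying
   to zero.
4. **RL/Pearce–Hall hybrid (PH).** A dynamic, non-Bayesian learning
   rate: an associability trace αₜ₊₁ = η|δₜ| + (1 − η)αₜ (initialized
   at α₁) scales the update E′ = E + min(1, κ·αₜ)δ.  Associability
   tracks |δ| in raw outcome points (0–100 scale), so κ·αₜ can exceed
   1; the effective rate is clipped at 1 to keep updates contractive.
   A `pe_scale` argument (default 1, i.e. raw points) can normalize δ
   inside the associability update for sensitivity checks.

**Decision rules** (choice task only): softmax
P(s) = exp(βEₛ)/Σ exp(βEₛ′), computed with max-subtraction.  The
constant rule has a single β; the dynamic rule sets βₜ = θ·(t/10)^c, so
θ is the inverse temperature on trial 10 and c ∈ [−2, 2] controls the
direction and speed of change (c > 0: exploration decreases over a
block).  Trial indices are 1-based everywhere to match the t/10 anchor.

## Hierarchical estimation

Each participant has their own parameter vector drawn from group-level
distributions; groups (e.g. adult-like vs adolescent-like) are fitted
separately.

* **Unit-interval parameters** (α, α₊, α₋, α₁, η, κ, β, θ, c′) get beta
  group distributions reparameterized as mean m = a/(a+b) and precision
  n = a+b, with hyperpriors m ~ Uniform(0, 1) and
  log n ~ Uniform(log 2, log 600).  The consistency parameter is
  estimated as c′ ∈ [0, 1] and mapped to c = 4c′ − 2.  β and θ are
  estimated on [0, 1] (a `beta_scale` configuration rescales the
  support for sensitivity analyses; default 1).  Outcome differences of
  10–20 points make β ≈ 0.2 already near-deterministic, so the unit
  support is not restrictive in these task designs.
* **Variance-type parameters** (ση², s₁², and the estimation-task
  reporting variance σ_r²) get half-Cauchy group distributions
  (location 0, nonnegative support) whose scale has a Uniform(0, 1000]
  hyperprior; individual values are drawn directly from the group
  half-Cauchy.
* **Likelihoods.** Estimation: reported estimates are Gaussian around
  the model's point predictions with per-participant variance σ_r²;
  expectations are initialized to the first estimate of each block, so
  trial 1 contributes a constant (it is retained so trial counts match
  the data layout).  Estimation fits are run separately per noise
  condition.  Choice: categorical softmax likelihood; both expectations
  start at 50, and only the chosen option's state updates.

**Sampler.** The backend contract is: consume the declarative fit
specification, return per-chain draws on the natural scale, respect the
seed.  The reference backend is an adaptive random-walk
Metropolis-within-Gibbs sampler (numba-compiled): each participant's
parameter vector is proposed jointly on transformed scales (logit /
log), with per-coordinate proposal SDs estimated from the chain's own
running variances (adaptive-Metropolis shaping, frozen at the end of
burn-in) and a global per-participant scale adapted toward 23%
acceptance; hyperparameters are updated one at a time toward 44%
acceptance, with three hyperparameter sweeps per iteration (they cost
no likelihood evaluations).  All adaptation stops at burn-in.  The
default contract is 3 chains × 40,000 samples, 20,000 burn-in, thinning
5 (12,000 retained draws); the `fast` profile (3 × 4,000 / 2,000 /
thin 2, 3,000 retained) is used by the recovery and comparison suites.
Convergence is checked with split R-hat (threshold 1.1); the remedy for
a failing fit is a single re-run with twice as many draws, and results
are flagged when this was applied.  With no data the sampler reproduces
its hyperpriors (checked by a Kolmogorov–Smirnov test against
Uniform(0,1)), and the Metropolis kernel is separately validated on a
conjugate Gaussian-mean toy with a closed-form posterior.

## Model comparison

DIC = D̄ + p_D with deviance D = −2 log L summed over all trials, D̄
the posterior mean deviance, and p_D = D̄ − D̂ the effective parameter
count, where D̂ is the deviance at posterior point estimates of the
*individual-level* parameters (hyperparameters integrated out), the
conventional focus when a hierarchical model is sampled trial-by-trial.
Point estimates are posterior means (canonical DIC); medians are
available as an option because downstream diagnostics use medians.
DIC values are mapped to model weights wᵢ ∝ exp(−Δᵢ/2).  Two caveats
discovered during validation are worth recording: (i) when a richer
model nests the generating one along an *exact* likelihood ridge (PH
with η → 0 mimics RL with α = κα₁ at any κα₁ product), the ridge
coordinates contribute nothing to p_D and DIC cannot penalize them —
comparisons should use variants whose extra parameters genuinely move
the likelihood; (ii) p_D is only ~1 per well-informed scalar parameter,
so weakly identified parameters are penalized less, by construction.

As an intuitive fit index, the package also computes the mean model
probability of the actually-made choices, running each model forward at
the posterior medians of the individual parameters.

## Behavioural metrics and cleaning

Empirical learning rates exclude the last trial of each block (no
further estimate follows) and zero-prediction-error trials.  For
regression-style analyses: estimates of 0 or above 100 are dropped
(out-of-range typing errors), the first certainty rating of the session
is dropped, and learning rates outside the per-group 1st–99th
percentile band are trimmed (linear-interpolation percentiles; boundary
ties retained; trimming is applied after the zero-δ̂ exclusions, since
a rate must exist to be trimmed).  Before model fitting, out-of-range
estimates are instead replaced by the average of the nearest valid
preceding and following estimates within the block (single neighbour at
block edges), preserving dataset length.  Choices are classified
exploitative/exploratory by comparing each option's running mean of
observed outcomes; trials before both options have been sampled, and
running-mean ties, are excluded.  The optimal learning rate in this
static task is 1/t — the gain that makes the estimate the running
sample mean (no drift, uninformative prior).

Because α̂ is a ratio, its trial-level distribution is heavy-tailed
even after trimming; group contrasts reported by the acceptance script
therefore summarize each participant by their median late-trial α̂
before averaging within group.

## Synthetic cohorts

The generator replaces the undeposited study data.  It emulates the two
published designs exactly (block counts, trial counts, SDs, mean
ranges) and simulates cohorts of agents whose parameters are drawn from
group-level distributions (beta via mean/precision; half-Cauchy via
scale).  The default cohort has 35 adult-like and 25 adolescent-like
participants; the adolescent-like group differs by a higher
drift-variance hypermean (half-Cauchy scale 0.1 vs 0.005) and a lower
inverse-temperature hypermean (θ mean 0.15 vs 0.35) — the qualitative
group structure the models are meant to detect.  Initial prior variance
is large in both groups (scale 300, i.e. ≫ 100 relative to σε² = 1:
first-trial gains near 1), and reporting noise has half-Cauchy scale 20
(median reporting SD ≈ 4.5 points).  Defaults not fixed by the task
designs were chosen once as realistic values and are not tuned.

Generative details the models do not see: the first-trial estimate is a
uniform guess on [20, 80] (there is nothing to base it on); reported
estimates are clipped to the 0–100 response interface, so extreme
reporting noise produces the boundary values the cleaning rules target;
certainty ratings are a monotone map of internal uncertainty — for
Kalman agents 10/(1 + s²) (the prior precision fraction scaled to the
rating range), for non-Bayesian agents a logistic function of trial
number — plus clipped Gaussian rating noise.  The certainty generator
is a stand-in for an unknown reporting process, not a substantive
claim.  Per-participant random streams are spawned from the master seed
by participant index, so cohorts are reproducible and
order-independent.

What passing tests on these cohorts do **not** show: real participants
presumably violate every model to some degree (lapses, reaction-time
dynamics, within-session drift of parameters, certainty-report biases),
and none of that misspecification is present in the generator.  The
validation demonstrates that the pipeline recovers what it assumes,
which is the standard and necessary — but not sufficient — check.

## Recovery suites

**Parameter recovery** simulates one cohort per grid point (default 10
points, 25 participants), refits the generating model with the fast
profile, and correlates generating against recovered group-level
central tendencies (posterior medians of the beta group means; the
half-Cauchy scale for variance parameters).  The default grids spread
each unit-interval hypermean over [0.15, 0.85] with a different seeded
permutation per parameter (spanning supports while decorrelating
parameters across points) and log-space drift-variance scales over
[0.002, 0.5]; the published simulation hyperpriors for these analyses
are not available, so the grids are the package's own and are always
logged with the results.  Measured at reduced scale: all four
hypermeans of the asymmetric-RL + dynamic-softmax model recover with
r ≥ 0.92; the hybrid model's associability parameters recover less
well (r ≈ 0.85, with θ and c′ ≈ 0.99), reproducing the qualitative
pattern that hybrid hyperparameters deserve more caution.

**Model recovery** simulates cohorts under each generating model, fits
every candidate, and tabulates DIC winners into a confusion matrix with
inversion confidences p(generating | winner).  Reduced-scale defaults:
10 cohorts × 25 participants per generating model, fast MCMC.

## Between-subject analyses

Individual drift-variance estimates are heavy-tailed, so the
cross-task analyses replace ση², θ and c by ranks (average ranks for
ties).  The single-level mediation (group → volatility → exploration)
estimates paths a, b, c, c′ by ordinary least squares (M ~ X and
Y ~ X + M), with ab = a·b and the exact OLS identity ab + c′ = c.
Inference is a percentile bootstrap over participants (default 10,000
resamples; a flag raises it to 100,000): percentile CIs and two-sided
p-values from the fraction of resampled path estimates crossing zero.
The percentile variant (rather than BCa) is the simplest to verify and
is conservative for the indirect path under the full null (measured
type-I rate ≈ 0.002 at nominal 0.05 over 500 null datasets — the
well-known conservatism of products of near-null coefficients).
Partial correlations are Pearson correlations of least-squares
residuals.

The default cohort draws volatility and exploration parameters
independently within group, so the mediation on it is genuinely null.
The acceptance script therefore demonstrates the analysis on a
"mechanism cohort" in which each participant's θ is a noisy decreasing
function of their own log drift variance (slope 0.08, noise SD 0.03,
log-drift SD 1.0, 40 per group) — strong enough coupling (true partial
r ≈ 0.9) to remain detectable after both variables are re-estimated
from behaviour, which attenuates rank correlations roughly by half.

## Problem sizes and numerical choices

The recovery, comparison and developmental analyses run at reduced
scale — 10–20 cohorts of 25–30 participants with the fast MCMC
profile — which the package treats as its default validation scale;
the full-contract profile is available everywhere via `MCMCConfig()`.
Degenerate inputs are defined, not special-cased: zero-trial datasets
sample the prior; zero prediction errors leave expectations unchanged
and are flagged in metrics; running-mean ties are excluded rather than
arbitrarily labelled; equal generating means make accuracy undefined
(NaN) rather than 0 or 1.  The gain recursion's convergence rate to its
fixed point is ≈ 1 − 2√(ση²/σε²) near the root, so closed-form
comparisons iterate to a tolerance rather than a fixed step count.
Likelihoods are computed in log space throughout; softmax probabilities
use max-subtraction.

## Known limitations

* DIC with individual-level focus cannot penalize parameters that sit
  on exact likelihood ridges (see above); WAIC/LOO are out of scope.
* Individual-level drift variances in low-volatility regimes are only
  weakly identified from 150 estimation trials; their posterior medians
  shrink toward the group scale, and group-level scales for
  adolescent-like (high) volatility are recovered with negative bias at
  reduced scale.
* The sampler is random-walk based: posteriors with strong funnel
  geometry (precision hyperparameters at small groups) mix more slowly
  than gradient-based samplers would; the doubling remedy and R-hat
  gate guard against silent failures.
* No reaction times, no eligibility traces or multi-step returns, no
  learning-noise model, no covariance between random effects, no joint
  fitting across tasks.
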