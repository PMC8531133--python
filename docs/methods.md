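# Methods

## The measurement model

Probability ratings are bounded at both ends of the response scale, so a
normal-likelihood regression is misspecified: variance must shrink near the
bounds and effects must saturate. We therefore model a rating `y ∈ (0,1)` as

    y_ij ~ Beta(μ_ij φ, (1 − μ_ij) φ)
    logit(μ_ij) = x_ij' β + u_i,     u_i ~ Normal(0, σ_u)

for observation `j` of participant `i`. `μ` is the cell mean on the
probability scale, `φ > 0` is a precision shared across cells (observation
variance `μ(1−μ)/(φ+1)`; a per-cell φ is available behind a flag for
sensitivity checks), and `u_i` is a participant random intercept capturing
the strong within-person correlation of threat expectations across events.
Random slopes are deliberately omitted: the design statement is observations
nested within participants, and six observations per participant cannot
support per-participant event profiles.

Two fixed-effect designs are supported, both treatment-coded:

- `exp2to5`: standardized fear-questionnaire score (`fear_z`, pooled
  z-scoring over both groups) plus `Group × Event` (12 cells + 1 slope).
- `exp1`: full `Fear Level × Rating Type × Event` factorial (24 cells).

Reference levels are the first group (Control / Low fear), the `belief`
rating type, and the first objective event (alphabetically); cell means for
prediction are formed from the coefficient vector by the same coding, so no
cell is privileged beyond the (arbitrary, documented) reference choice.

### Boundary handling

Ratings are divided by 100 and then compressed with
`(y(N−1) + 0.5)/N`, `N` = the number of observations in the table being
transformed (pooled over the fitted model's data by default; a per-event
scope is available). The map is strictly increasing, fixes 0.5, and sends
0 and 1 to `0.5/N` and `1 − 0.5/N`, so the beta likelihood is defined at the
bounds. It is applied exactly once — the pipeline marks transformed tables
and refuses a second application, since the map is not idempotent. Counted
bets on 0–50 scales are doubled to 0–100 before this step.

### Priors

The published analysis used weakly informative priors whose exact values are
in an unreproduced supplement; the defaults here are this package's own
choice with the same intent (keep logit-scale values plausible, speed
convergence) and are overridable per fit:

| parameter | prior | default rationale |
|---|---|---|
| coefficients β | Normal(0, 1.5) | ±3 logits ≈ probabilities 0.05–0.95 |
| σ_u | Half-Normal(1) | intercept spread rarely exceeds ~2 logits |
| φ | Gamma(2, rate 0.1) | mode 10, mean 20, long right tail |

For the two-group questionnaire model (Cohen's d), group means get
Normal(pooled mean, 10 × pooled SD) and group variances
InvGamma(0.5, 0.5 × mean within-group variance) — roughly half a
pseudo-observation, i.e. effectively diffuse at n ≥ 25, so the posterior
median of `d = (μ_1 − μ_2)/σ_pooled` tracks the classical pooled estimate.
The within-group (not total) variance scales the prior so the between-group
mean gap does not leak into the spread prior.

## Sampling

No probabilistic-programming backend is assumed: the hierarchical beta model
is sampled by a built-in No-U-Turn sampler (multinomial variant, dual
averaging to a 0.8 acceptance target, expanding-window diagonal mass
adaptation) on the unconstrained parameterization — non-centered intercepts
`u = σ_u z`, `log σ_u`, `log φ` — with analytic gradients (digamma terms of
the beta log-likelihood). Chains start from a shared penalized-likelihood
mode with the inverse diagonal Hessian as the initial mass matrix, plus
per-chain jitter. The two-group normal model uses a semi-conjugate Gibbs
sampler. Model seeds are independent of data seeds and both are recorded.

Convergence is a reporting contract, not an assumption: every fit computes
split-R̂ and bulk ESS (via arviz) for all reported parameters (coefficients,
σ_u, φ) and carries a `converged` flag requiring R̂ ≤ 1.01, bulk ESS ≥ 4000
and zero divergent transitions. Defaults are 4 chains × 4,000 post-warmup
draws (1,000 warmup): measured bulk ESS per draw for the slowest (intercept-
like) parameters of this sampler on these models is ≈ 0.3, so 16,000 draws
give the 4,000-ESS contract with headroom. Scaled-down settings used inside
simulation loops (2–4 chains × 250–300 draws) cannot and need not meet that
contract; interim fits in the sequential design instead require R̂ ≤ 1.05
and no excess divergences, otherwise the check is skipped and logged.

## Probability of Superiority

Raw (between-subject) PSup is the rescaled Mann–Whitney statistic — all
cross-group rating pairs, ties counted half, computed from joint ranks. The
within-subject variant couples observations by participant: the share of
participants whose rating in one condition exceeds the other (ties half).
Half-credit ties keep the complement identity `PSup(x,y) + PSup(y,x) = 1`
exact on slider data. Confidence intervals are bias-corrected accelerated
(BCa) bootstrap, resampling participants — the exchangeable units — with
10,000 resamples by default (z0 from the bootstrap distribution,
acceleration from delete-one jackknife influence values; degenerate
bootstrap distributions fall back to the percentile interval with a logged
warning).

Bayesian PSup: for every posterior draw, `n_pred` (default 1,000)
posterior-predictive ratings are generated per cell at a matched covariate
value (`fear_z = 0`, i.e. groups compared at identical questionnaire
scores), including beta observation noise and fresh participant intercepts
`Normal(0, σ_u^(draw))` (re-using fitted intercepts is available behind a
flag; the predictive question is about new participants). The empirical PSup
of the two prediction sets is one draw of the PSup posterior, summarized by
its median, 95% HDI and percentage of draws above 0.5 — the reporting triple
used in the figures. Interaction contrasts subtract PSup posteriors draw by
draw (e.g., mean of the three objective events minus mean of the three
subjective ones), which is valid because all PSup posteriors derive from the
same underlying draws.

The HDI is the shortest window containing ⌈level·n⌉ sorted samples, ties
broken toward the lowest start. A closed-form beta-vs-beta PSup
(`∫ f_X F_Y`, adaptive quadrature to 1e-8) provides the oracle against which
the empirical and posterior-predictive routes are tested.

## Sequential design

The simulator reproduces the pre-registered procedure: batches of
participants accrue (balanced across conditions by default; the real batches
were uneven, so the split is configurable); from the first scheduled check
(after batch 5, with the study's 50-per-condition minimum) the full pipeline
runs on all accumulated data — re-z-scoring the covariate over everyone
accrued — and collection stops when the 95% HDI of the signed
Objective−Subjective PSup contrast excludes 0, or at the 10-batch maximum.
A reference value other than 0 and an absolute-value variant of the rule are
available; note that a reference outside [−1, 1] is excluded by every HDI,
so the literal rule then stops at the first eligible check. Operating
characteristics (stopping distribution, false-positive rate, power) are
estimated by replicate simulation with Clopper–Pearson binomial intervals.

## The synthetic-data generator

The generator is the model's generative mirror plus the study's design
facts: two groups, six events (three objective, three subjective),
participant intercepts, a fear-score covariate entering linearly on the
logit scale, beta observation noise, and binary post-assessment choices.
Default conditions are chosen to resemble the published setting: 50
participants per group (the sequential design's per-condition target);
fear-score normals matching a short phobia questionnaire (mean 9, SD 3 in
both groups, as randomization implies); baseline event offsets putting
objective events near μ ≈ 0.35 and subjective events near μ ≈ 0.7; group
(manipulation) effects of −0.55 logits on objective and −0.12 on subjective
events (chosen to land the predictive PSup near the reported ≈ 0.67 / ≈ 0.55
per-event values); φ = 4 (broad slider spread); σ_u = 0.75; a 0.4
logit-per-SD fear slope; and an 85% "feelings" choice rate.

What it does *not* emulate: piling of real slider responses at 0, 50 and
100 (ratings are continuous and strictly interior unless integer rounding is
enabled); any response-quality pathology (bots, straight-lining — the
inclusion-tier machinery is exercised with synthetic check outcomes);
item-level questionnaire structure (totals only); uneven accrual. Passing
tests therefore demonstrate correctness of the estimators and calibration of
the pipeline under its own assumptions, not distributional fidelity to the
deposited data — the optional full-fidelity test against the deposit covers
that when a local copy is present.

Draw order (fear scores, then intercepts, then ratings in row order) is
fixed, so one integer seed reproduces every table byte-for-byte.

## Problem sizes used in the checked claims

Replicate-based claims run at deliberately reduced scale, chosen as the
smallest sizes at which the binomial tolerances are meaningful: 50
replicates (n = 50/group, 2 chains × 300 draws) for interval coverage; 20
replicates for null centering of the contrast (tolerance ±0.02 on the mean
of medians); an 8-replicate scaled sequential design (batches of 10 per
condition, checks after batches 2–3) for the null stopping rate; single
fits at n = 25–100/group for the convergence contract and
parameter-recovery spot checks. The moment-exact Cohen's d reconstructions
use the published group sizes as-is.

## Known limitations

- One shared φ means heteroskedasticity beyond the μ(1−μ) profile is
  unmodeled; the per-cell-φ flag exists but is untested against data.
- The empirical PSup inside the posterior loop uses finite `n_pred`, adding
  O(1/√n_pred) jitter per draw; it is negligible against posterior spread at
  the defaults but visible if both are made small.
- BCa acceleration uses the two-sample jackknife over pooled influence
  values; for very small groups (< ~8) the acceleration estimate is noisy.
- The sequential simulator treats interim non-convergence as a skipped
  check, which matches the registered procedure's spirit but has no
  published counterpart to validate against.
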