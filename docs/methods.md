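# Methods

## Model

`longdcm` implements a three-level longitudinal diagnostic classification
model.  Level 1 (items) is a log-linear cognitive diagnosis model (LCDM):
for item *i* with Q-matrix row *q_i*, the log-odds of a correct response is
the intercept plus main effects of the mastered attributes the item measures
plus a two-way interaction when both measured attributes are mastered.
Three-way and higher interactions are not supported: the reference design
caps items at two attributes.  Level 2 (occasions within persons) gives each
attribute *k* a linear-in-time logit of mastery,
`(gamma00_k + u0_rk) + (gamma10_k + u1_rk) * Time_rt`, with person-specific
real-valued measurement times, so unbalanced designs need no special
handling.  Level 3 (persons) draws the stacked random intercepts and slopes
from MVN(0, G), where G is 2K x 2K with effects ordered
(intercept, slope) nested within attribute — `u0_A1, u1_A1, u0_A2, ...` —
the ordering used in all fixtures, CSV headers and posterior labels.

Two readings matter throughout:

* **Residual variance.**  The level-2 residual with variance pi^2/3 is the
  variance *implied* by the logistic link in the latent-response
  formulation.  The generator and the likelihood therefore use
  Bernoulli-with-logit and never add a separate normal disturbance — adding
  one would double-count the residual.  `ResidualSpec(explicit=True)` exists
  for sensitivity analysis only.
* **Conditional vs marginal trajectories.**  `growth.mean_trajectory`
  evaluates the logit at the fixed effects with random effects at zero (the
  conditional-at-mean trajectory).  The population proportion of masters is
  the logistic-normal marginal `E_u[logistic(eta)]`
  (`growth.marginal_mastery_probability`, 1-D Gauss-Hermite with 41 nodes),
  which is attenuated toward 0.5 and the gap grows with time because the
  logit variance is quadratic in time.  A consequence worth flagging: with a
  zero average slope but nonzero slope variance (the "uneven" design's first
  attribute), the conditional trajectory is flat at 0.20 while the
  population proportion drifts from ~0.21 to ~0.42 across the five
  occasions.  The simulator is validated against the quadrature marginal,
  which is the statistically correct description of what it generates.

## Monotonicity and identification

Main effects are constrained nonnegative and each interaction bounded below
by minus the smaller of its two main effects, so mastering an attribute can
never lower the success probability.  The constraints are enforced at the
type level (`ItemParameters(..., enforce_monotone=False)` disables them for
research use) and in the sampler through truncated priors.  They also pin
the meaning of "mastery", so no post-hoc relabeling of latent classes is
needed.  Latent classes are enumerated with attribute 1 as the
fastest-varying bit (class c has profile bit k = (c >> k) & 1), fixed so
posterior output is comparable across runs.

## Synthetic-data generator

`simulate.generate` composes four seeded draws: (1) time scores
Normal(mu_t, sigma_time^2) i.i.d. per person-occasion (Normal is an
assumption; only the mean vector and SD are specified by the design);
(2) random effects MVN(0, G); (3) mastery indicators Bernoulli(logistic of
the person-occasion-attribute logit); (4) item responses Bernoulli(LCDM
probability of the person-occasion profile).  All randomness flows from one
`numpy` Generator seeded by the design, so reruns are bit-identical.  Time
scores are drawn independently across occasions without enforcing
monotonicity: with 8-week gaps and SD 1 the crossing probability is ~1e-8;
a warning fires if it happens.  The generating truth (mastery indicators
and probabilities, random effects) is stored on the returned data set so
evaluation never re-derives it.

Default design parameters (the package's study conditions): 3 attributes
measured by 30 binary items, 15 per attribute, each item measuring one or
two attributes; item intercepts -1.5, main effects 1.5, interactions 0.5
(correct-response probabilities 0.18 / 0.50 / 0.88); initial levels
gamma00 = (-1.38, -1.10, -0.85) (initial base-rates 0.20/0.25/0.30) with
weekly slopes (0.05, 0.04, 0.05) ("even") or (0, 0.04, 0.05) ("uneven");
intercept variances 0.15, slope variances 0.05, with an equal- or
unequal-correlation structure.  Of the two published renderings of the
unequal-correlation matrix only the one with both cross-attribute intercept
correlations at 0.90 is positive definite, so that is the one shipped.

What the generator does *not* emulate: missing data and dropout, local item
dependence across repeated administrations, polytomous responses, and
person covariates.  Passing tests therefore certify the estimator under a
correctly specified, complete-data model — not robustness to the
misspecifications real longitudinal assessments carry.

## Sampler

`infer.fit` runs a blocked Metropolis-within-Gibbs scheme per chain:

1. **Latent classes** — for every person-occasion cell the 2^K class is
   drawn exactly from its categorical full conditional (LCDM likelihood of
   the occasion's responses x growth-model prior logits), vectorized over
   all cells via one matrix product and Gumbel-max sampling.
2. **Item parameters** — scalar random-walk MH using per-class sufficient
   statistics (counts of correct/incorrect per latent class), so one step
   costs O(2^K) regardless of sample size.  The joint prior over an item's
   parameters is the product of normal kernels times the indicator of the
   monotonicity region; treating it as a single unnormalized density makes
   scalar MH exact even though the interaction's bound depends on the
   mains.
3. **Fixed effects** — scalar random-walk MH on the Bernoulli mastery
   likelihood.
4. **Random effects** — two complementary proposals, both vectorized over
   persons with per-person accept/reject (persons are conditionally
   independent given G): coordinate-wise steps, and a joint 2K-dimensional
   step preconditioned by the current Cholesky factor of G (the
   cross-attribute correlations reach 0.9, which coordinate moves handle
   poorly).
5. **Interweaving translation** — shift a fixed effect by delta and every
   person's matching random effect by -delta; the likelihood is invariant
   and acceptance is prior-driven.  This removes the slow trade-off between
   a fixed effect and the mean of its random effects.
6. **Parameter-expansion scale moves** — rescale a group of random-effect
   columns and the matching rows/columns of G jointly (groups: each column,
   all intercepts, all slopes, all columns).  The MVN quadratic form is
   invariant and the prior volume change cancels against the u Jacobian;
   acceptance combines the likelihood, the inverse-Wishart prior and the G
   Jacobian.  Without these moves the chain can linger for thousands of
   iterations in a low-variance basin where shrunken random effects and a
   small G reinforce each other.
7. **G** — conjugate inverse-Wishart full conditional given the random
   effects.

Numerical choices: log-likelihoods use `log1p(exp(.))` via `logaddexp` (no
overflow); linear predictors are clipped at +/-35 with a logged warning;
random-walk step sizes adapt every 50 burn-in iterations toward ~30%
acceptance and are frozen afterward, preserving detailed balance for the
kept draws.  Defaults: 3 chains x 4000 iterations, 2000 burn-in, thinning 1;
the `desk` preset (2 x 1500, 750 burn-in) completes a N=200, five-occasion
fit in ~15 s on one CPU.  Initialization is `heuristic` by default (mastery
scored against a 0.35 within-attribute correct rate, growth effects from
first/last-occasion logits, chain-specific jitter for dispersed starts);
`truth` and `random` modes exist for diagnostics.

Priors: item intercepts Normal(0, 2^2); mains Normal(0, 2^2) truncated to
[0, inf); interactions Normal(0, 2^2) truncated to the monotonicity region;
fixed effects Normal(0, 10^2); G inverse-Wishart(df = 2K + 2, scale = I).
`PriorSpec.with_g_center(G0, weight)` centers the inverse-Wishart mean on a
supplied matrix with `weight` pseudo-persons (default 1) — used by the
replication runs, which center on the generating G.  Whether G should be
sampled freely or informatively anchored is left to the caller; both modes
are first-class.

## Evaluation

* **Convergence** — the potential scale reduction factor is computed
  literally as `(n-1)/n + B/(nW)` with B = n x variance of chain means and
  W the mean within-chain variance; this equals the classical variance-ratio
  PSRF without the square root (available via `sqrt=True`).  A replication
  converges iff every monitored parameter (item parameters, fixed effects,
  unique G entries) has R-hat < 1.2; non-converged replications are dropped
  from condition summaries and the convergence rate is reported.
* **Classification** — posterior mastery probability is the average of the
  post-burn-in mastery indicator draws; status is mastery iff the
  probability strictly exceeds the 0.5 cutpoint (configurable).  Reports
  give the probability bias against the *generating* probability, the
  correct-classification rate among true masters and among true
  non-masters, and Cohen's kappa, reported as missing whenever either
  status has a single observed level (chance-corrected agreement is then
  undefined).
* **Recovery** — bias and MSE pool the posterior-mean errors over
  replications and over the members of each parameter set (item intercepts,
  mains, interactions; per-attribute growth intercepts and slopes; G
  variances and covariances), i.e. sum of (estimate - truth) over the set
  divided by the set size times replications.
* **Effect sizes** — factorial ANOVA on replication-level bias/MSE via an
  OLS sum-of-squares decomposition (main effects + two-way interactions;
  the study grid is balanced so no Type-III machinery), with partial
  eta^2 = SS_effect / (SS_effect + SS_residual) labeled
  small/medium/large at 0.01/0.06/0.14.

## Orchestration and problem sizes

`runner.run_condition` replicates one design cell (generate -> fit ->
diagnose -> score) with every replication's randomness a pure function of
(base seed, cell index, replication), so any replication can be re-run in
isolation and execution order cannot change results.  `runner.run_study`
assembles condition tables and the ANOVA per occasion stratum, writing
manifest-stamped CSVs and refusing to overwrite an existing study unless
forced.  The shipped presets are `paper-default` (100 replications, full
chains) and `desk` (3 replications, short chains); the package's own test
suite and acceptance script run at desk scale — 2-3 replications of the
N=200 five-occasion condition and single fits at N=100/300 — which is
sufficient for the closed-form checks, the simulator fidelity bounds at
20,000 persons, and classification/recovery comparisons at the tolerances
stated there.

## Known limitations

* Classification-rate and kappa values from 2-3 desk replications carry
  Monte-Carlo spread of a few hundredths; the full factorial at 100
  replications is the authoritative summary.
* The intercept of a hard, slowly-identified attribute (initial base-rate
  0.20) is estimated with negative bias because early-occasion mastery is
  shrunken toward non-mastery; centering time at the medial occasion
  (`growth.center_times`) mitigates this and is recommended for real data.
* Convergence *rates* depend on chain settings and priors and are not a
  target of the test suite.
* No missing-data handling, local item dependence, polytomous responses, or
  nonlinear growth.
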