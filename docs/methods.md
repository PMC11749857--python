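# Methods

`litbayes` implements a three-stage Bayesian workflow for evaluating
lymphocyte immunotherapy (LIT) in recurrent spontaneous abortion (RSA):
a categorical logistic regression with projection predictive feature
selection, a hierarchical random-effects meta-analysis of live-birth
relative risks, and a four-feature interaction ("empirical") model.  Because
the hospital cohort that motivates this design is not distributable, every
stage is paired with a synthetic-data generator with known ground truth, and
all quantitative claims in the test suite are claims about recovery of that
ground truth.

## Models

### Logistic regression over categorical factors

All covariates are categorical, coded in levels; the first level of each
factor denotes a missing measurement and is the reference level of the dummy
coding (for the treatment factor the reference is "untreated").  The model is

    logit P(y = 1 | x) = beta_0 + sum_i beta_i 1[x_i = level],

with independent normal priors: N(0, 1) on every level coefficient and
N(0, 2.5) on the intercept.  The N(0, 1) coefficient prior is the
weakly-informative default for level effects; the intercept scale 2.5 follows
common practice for logit-scale intercepts.  `PriorSpec.overrides` accepts
per-coefficient (location, scale) pairs so that informative,
literature-derived priors can be supplied without code changes.  Perfect
separation of a level is tolerated — the proper prior keeps the posterior
well defined — but logged as a warning.

### Sampler

Posteriors are sampled with a self-contained No-U-Turn sampler (NUTS):
slice-variant tree doubling, dual-averaging step-size adaptation targeting
0.8 acceptance (0.9 for the hierarchical meta-analysis, whose posterior can
be sharply curved near tau = 0), and windowed diagonal mass-matrix
adaptation during warmup.  Divergent transitions (energy error > 1000) and
max-tree-depth hits are counted and exposed.  Two implementation choices
matter for practical efficiency:

* **QR reparameterization.**  Dummy-coded designs make the intercept and
  indicator coefficients strongly correlated, which a diagonal mass matrix
  cannot absorb.  The logistic posterior is therefore sampled in the basis
  `gamma` with `X beta = Z gamma`, `Z = sqrt(n) Q` from a thin QR
  factorization, and draws mapped back to `beta`.  On the default cohort this
  cuts NUTS tree depth from ~2^7 to ~2^3 leapfrog steps per iteration.
  Rank-deficient designs (e.g. deliberately duplicated factors) fall back to
  the original basis, where the proper prior preserves identifiability.
* **Initial mass.**  The inverse Fisher information diagonal at p = 1/2 seeds
  the inverse mass matrix so warmup starts at the right scale.

Each chain draws from a `numpy` generator spawned deterministically from the
root seed; runs are bit-reproducible given (seed, chains, iterations).
"Iterations" counts total per chain including warmup, matching the convention
in which "4000 iterations with 2000 warmup" yields 2000 retained draws per
chain.  Chains 1..k-1 start from the prior location plus uniform jitter so
that split-R-hat sees overdispersed starts.

Correctness is established against independent oracles rather than another
MCMC code: dense-grid quadrature of 2-parameter logistic posteriors and of
the (mu, tau) marginal of the meta-analysis (agreement within 0.02 on
posterior means and SDs), closed-form fixed-effect pooling when tau = 0, and
closed-form autocorrelation times for the diagnostics.

### Diagnostics

Split-R-hat (rank-normalized) and effective sample size are computed via
ArviZ behind the package's own `split_rhat` / `ess` surface.  Constant chains
are flagged (R-hat = inf, ESS = 0, with a logged warning) instead of
propagating NaN.  Convergence thresholds are R-hat < 1.01 and ESS > 400,
current diagnostics practice; fits gate their summaries on them (the
meta-analysis withholds summaries on failure unless forced).  Bayesian R^2
for the binary outcome is computed on the probability scale,
var(p_hat) / (var(p_hat) + mean(p_hat(1 - p_hat))), per posterior draw; the
posterior predictive check simulates replicated outcome vectors and reports
the tail probability of the observed success proportion (and per-level
proportions) under the replicate distribution.

### Projection predictive feature selection

The full-factor fit is the *reference* model.  For a candidate factor subset,
each (evenly thinned) reference draw's fitted probabilities `mu_n` are
projected onto the submodel by minimizing the Bernoulli KL divergence — a
convex soft-label logistic fit solved by damped Newton iterations
(step-halving line search; a ridge-damped retry is logged if Newton fails).
The projection of the empty set reduces to the closed-form intercept-only
minimizer (the mean reference probability), which the tests verify; projected
KL is non-increasing under supersets by convexity.

Forward search greedily adds the candidate maximizing the in-sample projected
score — the reference-expected log predictive density of the submodel, i.e.
maximizing it is minimizing the projection KL.  Ties (within 1e-9) break by
fewer levels, then lexicographic name.  The search uses 20 projected draws
(cost); the *honest* per-size accuracy and ELPD curves are then computed by
stratified K-fold cross-validation (default K = 5; LOO-style evaluation is a
possible future backend): per fold the reference is refit on the training
split, projected onto each path prefix, and the held-out fold scored by the
p > 0.5 accuracy rule and ELPD = sum of log mean-over-draws pointwise
densities, reported as mean ± SD across folds (the error bars of a
selection-path plot; the paired fold design means these SDs reflect fold
variability, not independent replicates).

A consequence of projecting draw-by-draw is a noise floor: a pure-noise
factor still carries projected information of order the reference posterior's
coefficient variance, which scales like 1/n, while a real factor's projected
information is constant per observation.  Ranking consistency is therefore an
information question — the planted-truth benchmark uses n = 4000 so the
weakest planted factor's signal clears the floor — not a tuning dial.

### Hierarchical meta-analysis

Per study J with treatment counts d1/n1 and control counts d0/n0 the observed
log relative risk and its (known) variance are

    Y_J = ln(d1/n1) - ln(d0/n0),   sigma_J^2 = 1/d1 - 1/n1 + 1/d0 - 1/n0,

the standard delta-method variance of the log risk ratio.  A study with a
zero or arm-filling cell gets 0.5 added to all four cells (Haldane), logged
and recorded; an arm with n = 0 is an error.  The hierarchical model

    Y_J ~ Normal(theta_J, sigma_J^2),   theta_J ~ Normal(mu, tau^2)

carries a flat prior on mu and — because a flat prior on [0, infinity) is
improper — a uniform prior on tau over [0, 10] (log-RR scale), with a logged
sensitivity flag if posterior mass reaches above 5.  Sampling exploits the
conjugate normal–normal structure: NUTS draws (mu, tau) from the analytic
theta-marginal (tau through a scaled-logistic transform with its Jacobian in
the target), and each theta_J is then drawn exactly from its normal
conditional given (mu, tau, Y_J) — Rao-Blackwellization.  Joint samplers
over (mu, tau, theta) were rejected after testing: the centered and
non-centered parameterizations each have a funnel regime (non-centered NUTS
measurably under-visits large tau when studies are precise, because the
likelihood pins the auxiliaries on a ridge narrower than the adapted step
size; verified against an exact iid sampler built from the analytic
mu-marginal), whereas the collapsed target has no funnel at all.  The
reported draws still satisfy the non-centered identity
theta_J = mu + tau * eta_J with standard-normal eta_J.  Summaries follow the common
reporting convention: exp(mu) as posterior mean with central 95% interval;
tau as median (mean also emitted) with 95% interval.  Per-study shrinkage
summaries give exp(Y_J) with its Wald CI next to the posterior median and 95%
interval of exp(theta_J) (forest-plot content), plus the conditional-mean
diagnostic E[theta_J | mu, tau, Y_J] = (Y_J/sigma_J^2 + mu/tau^2) /
(1/sigma_J^2 + 1/tau^2) at posterior medians.  The new-study prediction
interval is the central 95% of exp(mu + tau z), z ~ N(0, 1) drawn fresh per
posterior draw.

The grid oracle integrates theta out analytically
(Y_J | mu, tau ~ Normal(mu, sigma_J^2 + tau^2)) and normalizes the joint
(mu, tau) density by trapezoid quadrature, erroring if posterior mass touches
the grid edge.  It is the independent check on every small-J MCMC fit.

One caveat the tests document: scaling all counts upward does *not*
unconditionally tighten the mu posterior, because shrinking sigma_J shifts
the tau posterior upward (spread previously absorbed by within-study noise is
reattributed to heterogeneity); the tightening claim holds conditionally on
tau and is tested with tau fixed.

### Interaction ("empirical") model

Main effects of treatment outcome x1 (untreated / treated without
blocking-antibody conversion, BA2 / treated with conversion, BA3), age band
x2 (missing, 19-27, 27-29, 29-31, 31-34, 34-57), paternal blood type x3
(missing, A, AB, B, O) and anticardiolipin antibody IgM x4 (missing,
negative, positive), plus interactions of x1 with each of x2..x4:

    logit p = beta_0 + sum_i beta_i x_i + sum_{j=2..4} alpha_j (x1 x x_j)

over non-reference levels: 1 + (2+5+4+2) + 2*(5+4+2) = 36 columns.  An
untreated patient contributes no interaction indicator (reference-level
annihilation).  Although the narrative description of this model mentions
only the treatment main effect alongside the interactions, the fitted
formula includes all four main effects — it nests the narrower description,
and omitting main effects under interactions would misattribute covariate
effects to the treatment.  Fitting and checking delegate to the shared
logistic engine; effect summaries report posterior means and central 95%
intervals per level, grouped into intercept / main / BA2-interaction /
BA3-interaction blocks with reference levels as exact zeros.

## Synthetic data

The generators define the package's study conditions:

* **Cohort.**  The default template has 12 factors: the four clinical
  factors above with effects mirroring the qualitative findings — treatment
  dominant (BA2 +0.6, BA3 +1.2; at least twice any competing effect), young
  age and blood type B and ACAIgM-positive favourable — plus eight nuisance
  factors (several pure noise), intercept -0.3, missing level at rate 0.1
  and remaining levels uniform (the marginal level frequencies of the real
  cohort are unknown; uniform is an explicit, arbitrary default).  The
  86-factor scale of the real cohort is reachable by passing a longer factor
  list; 12 keeps test runtimes in minutes.  Default n = 2000.  The
  planted-truth template (3 active factors with graded strong effects among
  9 noise factors) defaults to n = 4000 for the reason given above.
* **Studies.**  Twenty studies — 19 literature-scale (4246 patients) plus
  one hospital-cohort-scale (2316 patients), 6562 in total — with latent
  theta_J ~ Normal(ln 1.70, 0.42^2), the operating point of the published
  pooled analysis.  Control-arm risks cycle through 0.21-0.32, kept low
  enough that the risk-scale relative-risk link p1 = p0 exp(theta) stays
  inside (0, 1) for all but extreme latent draws; when it does not, p1 is
  clipped at 0.995 and the event logged (the log-RR link is unbounded on the
  risk scale, a known awkwardness of RR models).
* **Interactions.**  `generate_interaction_cohort` adds
  treatment-by-covariate log-odds offsets to the linear predictor before the
  outcome draw, for calibration and power tests of the interaction model.

One integer seed drives everything through `numpy.random.SeedSequence`
spawning (levels, outcomes, latent effects and counts on separate
substreams), so tables are bit-reproducible and the outcome redraw of the
interaction generator leaves factor columns untouched.

What the generators do *not* emulate: correlated factors (real examinations
cluster), informative missingness, the hospital's inclusion/exclusion
pipeline, calendar drift, or any clinical realism beyond categorical
structure.  Passing tests therefore demonstrate that the machinery recovers
known structure under the models' own assumptions — not that the models are
adequate for any particular real cohort.

## Numerical choices and problem sizes

* Logistic targets use `logaddexp` for the log-partition; projection KL clips
  probabilities at 1e-12; the tau transform uses softplus-stable Jacobians.
* Default sampler configuration mirrors the published setting (4 chains x
  4000 iterations, 2000 warmup).  Test and example fits use 2-4 chains and
  400-2000 retained draws — enough for the assertions' Monte Carlo error at
  desk scale; the parameter-recovery study runs 100 simulated meta-datasets
  at 2 chains x 1200, and the selection benchmarks 25 replicates each.
* Forward-search ties break (fewer levels, then name); cross-validation folds
  are stratified by outcome and error out if a fold would be single-class.
* Grid oracles use 200-400 point axes bracketing the posterior, with an edge
  mass guard at 1e-3.

## Known limitations

* No continuous covariates (everything is discretized into levels) and no
  hierarchical terms in the logistic model.
* The forward search evaluates no interaction terms; the interaction model's
  four factors are fixed by specification, not searched.
* PSIS-LOO evaluation and projpred-style draw clustering are not implemented;
  cross-validation stands in for both.
* Reproducing the published real-cohort numbers (ELPD -1378.8, accuracy 0.69,
  and the per-study counts behind the pooled relative risk 1.70) requires the
  original hospital dataset and supplementary study table, which are not
  redistributed here; the test suite documents where that table would be
  placed (`data/source_meta_studies.csv`) and otherwise substitutes
  property-based recovery checks at the same operating point.
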