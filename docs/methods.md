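# Methods

## Data model

A cohort is a table of patient records with a binary outcome (1 = natural
dental caries, 0 = non-natural) and five categorical covariates with fixed
level sets: gender {Female, Male}, residence {Urban, Rural}, region
{Others, SNNPR}, age group {<18, 18-25, 26-35, >=35} and teeth-cleaning
habit {No, Yes}.  Validation happens at construction: any value outside
its level set, or any missing cell, raises an error naming the row and
column.  Level matching is case-insensitive, dashes are normalised, and
the age-group spellings that vary across the source material ("<=18",
"≤ 18", en dashes, "> = 35") are canonicalised to one form at read time.

Reference coding uses the first level of each covariate (Female, Urban,
Others, <18, No) as the reference, yielding 8 coefficient slots in fixed
order: `intercept, Male, Rural, SNNPR, 18-25, 26-35, >=35, Yes`.

## Synthetic cohorts

The clinic data behind the published tables were never deposited, so the
generator emulates their statistical structure rather than the data
themselves:

* covariates are drawn **independently**, each from its published marginal
  frequency (level totals / 6007).  Only marginal counts were published;
  the generator makes no guess at the joint distribution.
* the outcome is Bernoulli with P(y=1) = expit(xᵀβ), where the default β
  are the study's reported posterior means
  (1.726, −0.2038, −0.3699, 0.4957, −0.484, −0.3205, −0.2887, 0.389).
* defaults: n = 6007, seed 20190107; all randomness flows through one
  PCG64 generator, so a fixed seed reproduces cohorts bit-for-bit.

Because the real covariates are surely dependent, the independent-marginal
default implies a simulated prevalence near 0.78–0.80 rather than the
observed 0.87.  `calibrate_intercept` bisects on the intercept until the
Monte-Carlo mean of expit(xᵀβ) over 10⁵ covariate draws matches a target
prevalence (tolerance 0.005) for users who need prevalence-matched
fixtures; it is deliberately opt-in so that default cohorts carry the
literal published coefficients.

Consequently, passing tests on synthetic cohorts demonstrate that the
estimators recover the generating model under the published marginal
structure; they cannot certify behaviour under the unknown covariate
dependence of the real clinic population.

## Classical fitters

All three models share one Newton–Raphson core: iterate
β ← β + I(β)⁻¹U(β) with step-halving (up to 20 halvings) whenever a
proposed step leaves the parameter space or decreases the log-likelihood;
declare convergence when max|U(β)| < tol (default 1e-8, max 100
iterations); report standard errors from the inverse information at the
optimum.  Starting values are zeros for the logistic model; for the log
link models the intercept starts at ln(mean(y)) with zero slopes, which is
always interior.  Estimates whose magnitude exceeds 30 — beyond any
plausible epidemiological log-effect — raise an explicit separation error.

Model specifics:

* **Logistic**: canonical link, observed = expected information.
* **Log-binomial**: the information is the Fisher (expected) form with
  weights p/(1−p); the observed information weights p(1−y)/(1−p)² vanish
  on successes and make iterations fragile near the boundary, while the
  expected form is the standard scoring choice and coincides with the
  observed one in expectation.  A boundary optimum (any fitted probability
  pinned at 1) is reported via `converged=False` plus a message, never as
  a silent estimate.
* **Robust Poisson**: Poisson score and information for the point
  estimates; covariance from the HC0 sandwich A⁻¹BA⁻¹ with A the
  model-based information and B the outer product of per-record scores.
  No small-sample correction is applied.  On saturated categorical
  designs the sandwich reproduces the binomial variance exactly — the
  correction matters relative to the naive Poisson variance, which
  overstates Bernoulli noise by a factor 1/(1−p) per cell.

Crude 2×2 measures (`crude_odds_ratio`, `crude_risk_ratio`) take the
layout rows = (reference, index) exposure, columns = (non-natural,
natural).  A zero cell raises by default; the Haldane–Anscombe +0.5
correction is available behind an explicit flag because silent correction
hides data problems.

## Bayesian model and sampler

Likelihood: Bernoulli-logit, computed as Σ y_iη_i − softplus(η_i) with
`logaddexp`, finite for any |η|.  Prior: independent β_j ~ N(μ_j, σ²_j),
default μ = 0, σ² = 1000 — vague enough that the posterior essentially
reproduces maximum likelihood at n = 6007.  The log-posterior is the sum
of the two; all density work is in log space.

The posterior has no conjugate full conditionals, so sampling is
Metropolis-within-Gibbs: each sweep updates one coordinate at a time with
a normal random-walk proposal accepted by the usual ratio of unnormalised
posteriors.  Two design choices matter:

* **Sweep directions.** The intercept is strongly correlated with every
  dummy coefficient a posteriori, and raw axis-aligned single-site updates
  mix slowly (thin-50 draws retained lag-1 autocorrelation ≈ 0.26 for the
  intercept).  The default sweep therefore updates one coordinate of the
  *Cholesky-decorrelated* basis per step: directions are the columns of
  the Cholesky factor of the MLE covariance, so each update is still a
  one-dimensional normal-proposal Metropolis move, but along directions
  in which the posterior is nearly independent.  `proposal="axis"`
  restores literal coefficient-axis updates.
* **Adaptation.** Proposal scales start at 2.4 (whitened basis; 2.4·SE on
  raw axes) and are multiplied by exp(rate − 0.44) every 50 burn-in
  sweeps, targeting the 0.44 acceptance rate that is optimal for
  one-dimensional random-walk Metropolis; scales freeze at the end of
  burn-in so the retained chain is a genuine Markov chain.  Acceptance
  pinned at 0 or 1 after burn-in raises an adaptation error.

Defaults: 3 chains, 5000 burn-in sweeps, 10 000 post-burn-in sweeps,
thinning 50 (200 stored draws per chain, 600 pooled).  Chain c draws from
the stream `default_rng([seed, c])`, so runs are exactly reproducible.
Chain 1 starts at the MLE, the others at MLE ± 2 SE per slot, giving the
overdispersed starts the Gelman–Rubin diagnostic assumes.  At least two
chains are required.

Summaries over pooled draws: mean, SD, median; MC error by batch means
with ⌊√N⌋ batches; HPD as the shortest window of ⌈mass·N⌉ consecutive
sorted draws.  Fewer than 100 pooled draws raise, as summaries would be
unreliable.

## Diagnostics

* **Autocorrelation**: sample ACF with overall-mean centering, lag-0
  normalisation; a constant series is defined to have ACF 1 at lag 0 and
  0 elsewhere.
* **Gelman–Rubin**: the classic un-split, un-rank-normalised PSRF.  With
  W the mean within-chain variance and B/n the variance of chain means,
  R̂ = sqrt(((n−1)/n·W + B/n)/W), floored at 1 (the pooled estimate dips
  below W by the (n−1)/n factor alone when chains agree).  Threshold 1.1
  by default; requires ≥ 2 chains.
* **Thinning check**: the autocorrelation at the thinning lag is
  estimated from the full unthinned post-burn-in series (10 000 sweeps)
  rather than from the 200 stored draws: both estimate the same quantity,
  but the full-series estimate has sampling noise ≈ 0.02 against ≈ 0.07,
  which is what a 0.1 threshold needs to be meaningful.  For draws loaded
  from disk (where only thinned values exist) the report falls back to
  the lag-1 ACF of stored draws averaged over chains.
* **Density series**: Gaussian KDE with Silverman bandwidth on pooled
  draws, exported as numeric grids so the diagnostics are testable
  without a graphics stack; `dentalrisk.plots` renders optional
  trace/density/ACF panels.

## Comparison table

`compare` aligns MLE estimate/SE/Wald interval with posterior
mean/SD/HPD per slot and reports interval lengths, their differences, and
the count of slots where the HPD is shorter.  The count is an observation,
not an assertion: with σ² = 1000 the two intervals agree to a few percent
and the direction flips by Monte-Carlo noise.

## Problem sizes used in the test suite

The within-run agreement and convergence checks use one default-size run
(n = 6007, 3 chains, default sweep counts).  The coverage study uses 20
replicate cohorts with 2 chains × (1000 burn-in + 4000 kept, thin 10)
each — 800 pooled draws per replicate, enough to locate a 95% HPD to the
precision the ±8 percentage-point acceptance band requires, with 160
slot-by-replicate coverage events in total.

## Known limitations

* Covariate independence in the generator is a simplification; the real
  joint distribution is unknown.
* The log-binomial fitter reports boundary optima honestly but does not
  implement constrained (boundary) maximum likelihood.
* No Firth correction or exact logistic regression for separated data;
  separation raises.
* Diagnostics are limited to the four named above — no Geweke,
  Heidelberger–Welch or effective-sample-size machinery beyond batch
  means.
* The CLI loads whole cohorts into memory; it is sized for
  epidemiological tables, not streaming data.
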