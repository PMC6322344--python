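# dentalrisk

Classical and Bayesian regression analysis of risk factors for dental
caries, built for epidemiologists comparing effect-measure estimators on a
common binary outcome.

The motivating data are a retrospective cohort of 6007 dental-caries
patients from a higher clinic in Hawassa, Ethiopia, with a binary outcome —
*natural* caries (y = 1) versus *non-natural* caries (y = 0) — and five
categorical risk factors: gender, place of residence (urban/rural), region
(SNNPR vs others), age group (<18, 18–25, 26–35, ≥35) and teeth-cleaning
habit.  The patient-level data were never deposited, so the package ships a
seeded synthetic-cohort generator that reproduces the study's published
marginal structure, and all published counts and coefficients are carried
as reference inputs.

## Models

With reference coding (Female, Urban, Others, <18, No absorbed into the
intercept) and linear predictor η_i = x_iᵀβ over the 8 slots
`intercept, Male, Rural, SNNPR, 18-25, 26-35, >=35, Yes`:

* **Logistic regression** — logit P(y_i = 1) = η_i; exp(β_j) is an odds
  ratio (OR).
* **Log-binomial regression** — log P(y_i = 1) = η_i; exp(β_j) is a risk
  ratio (RR).  The log link bounds fitted probabilities below 1, so the
  Newton–Raphson fitter step-halves at the boundary and flags boundary
  optima instead of returning a silently wrong answer.
* **Robust (modified) Poisson regression** — Poisson working likelihood on
  the binary outcome; point estimates are consistent RR estimates and
  standard errors come from the HC0 sandwich A⁻¹BA⁻¹.
* **Bayesian logistic regression** — Bernoulli-logit likelihood with
  independent β_j ~ N(0, 1000) priors, sampled by Metropolis-within-Gibbs
  (one-coordinate random-walk Metropolis updates, proposal scales adapted
  toward 0.44 acceptance during burn-in).  Posterior tables report mean,
  SD, batch-means MC error, median and the 95% highest-posterior-density
  (HPD) interval; convergence is checked by trace, density,
  autocorrelation and Gelman–Rubin R̂ diagnostics.

All fitters are written from first principles (statsmodels is used only as
an independent cross-check in the test suite).

## Worked example

```python
import dentalrisk as dr

cohort = dr.generate_cohort(dr.GeneratorConfig(seed=42))   # n = 6007
fit = dr.LogisticModel.from_cohort(cohort).fit()
print(fit.summary())

posterior = dr.BayesianLogit.from_cohort(cohort).fit(dr.ChainConfig(seed=43))
print(posterior.summary().round(4))
table = dr.compare(fit, posterior.summary())
```

The classical fit prints (abridged):

```
logistic regression  (converged=True, iterations=6, log-likelihood=-3097.4388)
effect measure: OR = exp(estimate)
     slot  estimate     se       z      p   lower   upper  effect_measure
intercept    1.7946 0.0969 18.5190 0.0000  1.6047  1.9846          6.0172
     Male   -0.2426 0.0635 -3.8208 0.0001 -0.3671 -0.1182          0.7846
    Rural   -0.3890 0.0646 -6.0175 0.0000 -0.5157 -0.2623          0.6777
```

so males have an estimated OR of 0.78 relative to females (odds of natural
caries 22% lower), and rural patients an OR of 0.68 relative to urban.
The posterior summary for the same cohort:

```
             mean      sd  mc_error  median  hpd_lower  hpd_upper
intercept  1.7918  0.0928    0.0034  1.7912     1.6141     1.9733
Male      -0.2440  0.0643    0.0029 -0.2432    -0.3634    -0.1239
Rural     -0.3881  0.0673    0.0030 -0.3878    -0.5112    -0.2540
```

With the vague prior the posterior means and SDs track the MLEs and their
SEs to within a few percent (max Gelman–Rubin R̂ here: 1.0025), and the
comparison table reported the HPD interval shorter than the Wald interval
in 6 of 8 slots — the two interval types are near-identical at this sample
size and the direction can flip with Monte-Carlo noise.

A shell pipeline producing the same artifacts end to end:

```sh
dentalrisk pipeline --seed 42 --out results/run1
```

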