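# hazglm

Flexible parametric modelling and extrapolation of hazard functions from
time-to-event data, built on generalized linear models (GLMs) over life
tables.

## Who this is for

Analysts who need parametric hazard estimates that extrapolate beyond the
observed follow-up — the typical setting in health technology assessment,
where mean survival over a lifetime horizon drives cost-effectiveness
results but trial follow-up ends after a few years. Standard one- and
two-parameter survival models (exponential, Weibull, Gompertz,
log-logistic, lognormal) impose linearity of the (transformed) hazard in
(transformed) time and can misrepresent complex hazard shapes; this package
provides them alongside strictly more flexible alternatives in one
framework, on one likelihood scale, with one comparison workflow.

## The model

Individual records `(tᵢ, δᵢ)` (follow-up time in years, event indicator)
are restructured into a monthly life table: for interval *t*, `y_t` events,
`c_t` censorings, `n_t` subjects entering, and actuarial at-risk exposure

    τ_t = n_t − c_t / 2,     λ_t = y_t / τ_t .

The hazard is then modelled as a Poisson GLM with a log link and `log τ_t`
as offset,

    y_t ~ Poisson(λ_t τ_t),      log λ_t = x_tᵀ β ,

where the time covariate `x_t` (evaluated at the interval midpoint)
determines the model: none (exponential), `t` (Gompertz), `log t`
(Weibull). Censoring needs no likelihood term — it only reduces exposure.
A binomial pathway for cumulative failures (logit → log-logistic, probit →
lognormal) is also implemented.

Beyond the linear designs:

- **Fractional polynomials** `log λ(t) = β₀ + Σ βⱼ t^{pⱼ}` with powers from
  {−2, −1, −½, 0, ½, 1, 2, 3} (0 ≡ log), order fixed by a closed-test
  procedure and powers by AIC;
- **Restricted cubic splines** with percentile knots on the uncensored
  event times, knot count by AIC;
- **Penalized GAMs** (cubic B-spline basis, integrated squared second
  derivative penalty) reporting effective degrees of freedom;
- **Interval-level frailty**: a Gaussian random intercept per interval,
  estimated by Laplace-approximate marginal likelihood;
- **Dynamic survival models**: the log hazard as a latent state
  (local level / level with drift / level + trend) filtered by the
  conjugate-gamma Poisson update, with hyperparameters tuned to minimize
  one-step-ahead forecast error;
- classical **gamma, generalized gamma, generalized F, lognormal and
  log-logistic** hazards fit by maximizing the same Poisson life-table
  likelihood, so AICs are comparable across the whole suite.

Models are compared by AIC (full data and a 3-year training split), by
sum of squared errors between predicted and observed monthly hazards over
a holdout window (months 37–88 by default, reported ×10⁴), and by mean
life expectancy from actuarial integration of the extrapolated survival
curve.

## Worked example

```python
import hazglm as hg

records = hg.gbsg_like(seed=1)          # 686-subject synthetic cohort
lt = hg.build_lifetable(records)        # monthly life table

family, design = hg.standard_spec("weibull")
m = hg.fit_glm(lt, family, design, name="weibull")
print(m.beta.round(3), round(m.loglik, 2), round(m.aic, 2))
# [-4.827  0.078] -159.17 322.34

fp = hg.select_fp(lt)                   # closed-test fractional polynomial
print(fp.extra["closed_test_stage"], fp.extra["powers"], round(fp.aic, 2))
# fp1 [-2.0] 307.75

from hazglm.evaluation import life_expectancy
print(round(life_expectancy(fp), 2))    # mean survival, 100-year horizon
# 9.53
```

The Weibull fit's log-time coefficient 0.078 says the log hazard is nearly
flat in log time (shape ≈ 1.08); the closed test instead selects a
one-term fractional polynomial in `t⁻²` — a hazard that rises from zero
and levels off — improving AIC from 322.3 to 307.8. The life expectancy is
the area under that model's extrapolated survival curve.

The same workflow is available from the shell:

```sh
hazglm simulate --scenario gbsg --seed 1 -o records.csv
hazglm lifetable records.csv -o lifetable.csv
hazglm compare records.csv -o results/       # full 11-model comparison
hazglm extrapolate records.csv -m lognormal --horizon 20 -o extrap.csv
```

`hazglm compare` writes a comparison table (model, logL, parameters,
full-data AIC, training AIC, holdout SSE ×10⁴, life expectancy) and tidy
hazard-curve CSVs for plotting.

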