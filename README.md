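# icaipw

Doubly robust semiparametric regression on cumulative incidence
functions (CIFs) for **interval-censored competing-risks data with
missing event types**.

## The problem

In cohort studies with periodic examinations (HIV care programs,
registry follow-up, electronic health records), an event is rarely
observed at its exact time: it is only known to have happened between
the last visit before it (`V`) and the first visit after it (`U`), or
never during follow-up (right censoring), or before the first visit
(left censoring).  On top of that, the *type* of the event is often
missing for a subset of subjects — for example when deaths are
under-reported and only a double-sampled subset of dropouts is traced.
Dropping those subjects (a complete-case analysis) removes *events
only*, never censored subjects, and is therefore systematically biased.

`icaipw` implements an augmented inverse-probability-weighted (AIPW)
sieve maximum-likelihood estimator for this setting, together with the
complete-case (CC) and multiple-imputation (MI) benchmarks and a fully
specified synthetic-data generator for Monte Carlo evaluation.

## The model

For each cause `j = 1..k` the CIF `F_j(t; z) = Pr(T <= t, eps = j | z)`
follows a generalized odds-rate transformation model

    g(F_j(t; z); alpha_j) = phi_j(t) + beta_j' z,

where `g(.; alpha)` interpolates between the Fine–Gray/cloglog link
(`alpha = 0`) and the proportional-odds logit link (`alpha = 1`,
default).  The baseline transforms `phi_j` are unspecified increasing
functions, estimated over a monotone B-spline sieve (order `m = 4`,
`ceil(n^0.2)` interior knots at percentiles of the pooled observation
times, strictly increasing coefficients).

With missing event types the cause indicators in the log-likelihood are
replaced by AIPW weights built from two working models fitted in a first
stage on the events:

* `rho(O; xi)  = Pr(R = 1 | Delta = 1, O)` — logistic response
  (nonmissingness) model;
* `pi_j(O; psi) = Pr(eps = j | Delta = 1, O)` — logistic (or
  multinomial) event-type model;

with `O = (U, Z, A)` including auxiliary covariates `A` that predict
missingness.  The weighted objective is maximized subject to
`sum_j F_j(b; z) < 1` over the observed covariate patterns.  The
estimator is **doubly robust**: consistent when either `rho` or `pi` is
correctly specified.  Standard errors come from the nonparametric (or
double-sampling-stratified) bootstrap.

## Worked example

```python
import numpy as np
from icaipw import SimScenario, simulate_dataset, fit_aipw, bootstrap_variance, FitConfig

ds = simulate_dataset(SimScenario(n=400, seed=7))      # 2 causes, 30% missing types
fit = fit_aipw(ds, FitConfig(seed=0))
fit = bootstrap_variance(ds, FitConfig(seed=0), B=100, fit=fit, seed=1)
for name, b, se in zip(["b11", "b12", "b21", "b22"], fit.beta_hat, fit.se_beta):
    print(f"{name}: {b:+.3f} (SE {se:.3f})")
```

prints (true coefficients `(0.5, -0.3, -0.5, 0.3)`):

```
b11: +0.434 (SE 0.278)
b12: -0.269 (SE 0.148)
b21: -0.465 (SE 0.276)
b22: +0.275 (SE 0.127)
```

Each coefficient is the effect of the covariate on the odds-rate scale
of the corresponding CIF; the bootstrap SEs feed Wald 95% intervals.
The same interface runs on delimited files through the CLI:

```bash
icaipw simulate --n 400 --seed 7 --out cohort.csv
icaipw fit --data cohort.csv --method aipw --bootstrap 100 --out results
icaipw simstudy --methods aipw,cc,mi --reps 200 --out study/
```

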