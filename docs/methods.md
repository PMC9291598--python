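# Methods

## Model and observed data

Competing-risks data with `k` mutually exclusive event types are
observed under interval censoring: each subject carries `(V, U)` — the
last examination before and the first examination after the event —
with `V = 0` for left-censored events and `U = inf` for right-censored
subjects.  The event type `eps` may be missing (response indicator
`R = 0`), but only for events: the right-censoring status itself is
always observed.  Missingness is assumed *missing at random* given the
fully observed quantities `O = (U, Z, A)`: the probability of observing
the type may depend on the detection time, the covariates of interest,
and auxiliary covariates `A` (for instance the number of outreach
workers in a double-sampling design), but not on the unobserved type
itself.  Allowing `A` into the mechanism weakens the MAR assumption
relative to conditioning on `(U, Z)` alone.

The cause-`j` CIF follows the generalized odds-rate transformation model
`g(F_j(t;z); alpha_j) = phi_j(t) + beta_j' z` with

    g(F; alpha) = log{ ((1-F)^(-alpha) - 1) / alpha },   alpha > 0
    g(F; 0)     = log{ -log(1-F) },

a family that contains the Fine–Gray subdistribution-hazards model
(`alpha = 0`) and the proportional-odds model (`alpha = 1`).  The
exponents `alpha_j` are user-fixed model indices (default 1), not
estimated.  Internally `F` is clamped to `[1e-10, 1 - 1e-10]` so that
optimizer line searches cannot produce infinities.

## Sieve for the baseline transforms

Each `phi_j` is represented as a B-spline of order `m = 4` (cubic) on
`[0, b]`, `b` the largest finite observation time, with boundary knots
of multiplicity `m` (clamped, so `phi(0)` and `phi(b)` equal the
extreme coefficients) and `N_n = ceil(n^nu)` interior knots at the
`j/(N_n+1)` percentiles of the pooled finite observation times
`{V_i, U_i}`.  The rate exponent is `nu = 1/(1+2p)` with smoothness
`p = 2`, hence `nu = 0.2`; both `m` and `nu` (and an explicit `N_n`
override) are exposed in `FitConfig` since no canonical choice exists
for a given data set.  Tied percentiles reduce `N_n` with a logged
warning.

Monotonicity of `phi_j` is equivalent to strictly increasing spline
coefficients.  Rather than imposing `N_n + m - 1` linear constraints,
the optimizer works in an unconstrained reparameterization
`gamma_1 = raw_1`, `gamma_{s+1} = gamma_s + exp(raw_{s+1}) + delta`
with a minimum gap `delta = 1e-6` that keeps "strictly increasing"
numerically meaningful.  The map is a smooth bijection onto the
admissible set, and gradients are chain-ruled through it analytically.

## Two-stage estimation

**Stage 1.** The response model `rho` is a binary-logistic ML fit of
`R` on the `Delta = 1` subset; the event-type model `pi` is a logistic
(`k = 2`) or multinomial (`k > 2`) ML fit on the complete events
(`R = 1, Delta = 1`).  The default design for both is
intercept + `U` + `Z` + `A`; term lists are configurable, and a
*saturated* option fits one free probability per observed cell of a
discrete design (used by the double-robustness diagnostics).  For
left-censored events `U` is their first visit time; the event-type
model is shared across censoring classes.  Fitted probabilities are
clipped to `[1e-3, 1 - 1e-3]` before being inverted into weights —
near-zero response probabilities would otherwise dominate the
objective — and clipping is logged when active.  If no event type is
missing, stage 1 short-circuits and the estimator reduces exactly to
the complete-data sieve MLE.

**Stage 2.** The cause-by-class indicators in the complete-data
log-likelihood

    sum_j D1_j log{F_j(U)-F_j(V)} + sum_j D2_j log F_j(U)
      + (1-D) log{1 - sum_j F_j(V)}

are replaced by the AIPW weights, applied to the record's observed
censoring class `l`:

    D~_j^(l) = D^(l) [ (R/rho) 1{eps=j} - ((R - rho)/rho) pi_j(O) ].

Restricting the augmentation to the observed class makes the weights
conserve mass — summed over causes and classes they equal one for every
event, exactly as the indicators they replace — and is the version under
which the double-robustness argument goes through; applying the
augmentation to both classes would double-count it.  Right-censored
subjects enter unweighted.  The mean-weighted objective is maximized
over (reparameterized `gamma_j`, `beta_j`) by SLSQP under the joint
feasibility constraint `1 - sum_j F_j(b; z) > 0` evaluated at every
*observed* covariate row (the supremum over an unbounded continuous
covariate space is not computable; the observed rows are the ones the
likelihood actually touches), with an enforced slack of `1e-6` and an
analytic constraint Jacobian.  Because the spline is clamped,
`phi_j(b)` is just the last coefficient, which keeps the constraint
cheap.

Numerical safeguards, all config-exposed:

* logs are linearized below `1e-10` (`C^1` extension), so transiently
  infeasible line-search points stay finite with consistent gradients;
* negative weights (possible for AIPW) can reward a vanishing
  probability difference for one record; the linearized log bounds that
  reward while the positively weighted records dominate;
* a loose parameter box (`raw` increments <= 6, `|beta| <= 15`) is never
  active at a sensible optimum but prevents `exp` overflow during wild
  line searches;
* initialization: `beta = 0` and baseline CIFs rising from 0.01 to
  `0.3/k` — always feasible; up to 3 jittered restarts (seeded), after
  which a feasible near-stationary iterate is accepted or a
  nonconvergence error carrying the best iterate is raised;
* convergence tolerance `1e-8` on the objective.

Gradients of the objective are analytic throughout (the inverse-link
derivative is `e^eta (1-F)^(1+alpha)`), with a finite-difference path
behind a config switch; the test suite checks agreement to `1e-4` at
random feasible points.

**Variance.** Nonparametric bootstrap with a full two-stage refit per
replicate, warm-started at the original estimate; Wald 95% intervals
use `beta +- 1.96 SE`.  When double sampling fixes the number of traced
subjects by design, a stratified variant resamples separately within
the observed-type events, missing-type events, and the right-censored
pool, preserving stratum sizes.  Replicates that fail to converge are
dropped and counted (warning above 20% failures, error above 50%).

## Comparators

*Complete case* drops the `R = 0` records (all of them events) and runs
the complete-data sieve MLE — biased by construction whenever
missingness is not completely random, since censored subjects are never
dropped.  *Multiple imputation* draws each missing type from the fitted
event-type model, by default *properly* (model coefficients redrawn per
imputation from their asymptotic normal; the improper variant is a
flag), fits the complete-data MLE per completed dataset (M = 5 by
default) and pools with Rubin's rules `T = W + (1 + 1/M) B`, with the
within-imputation variance from the same bootstrap engine.

## Synthetic-data generator

The generator emulates a two-cause cohort with proportional-odds CIFs
and improper-Gompertz baselines `exp{phi_j(t)} =
-(tau_j/rho_j){1 - exp(rho_j t)}`, defaults `(tau_1, rho_1) =
(0.40, -0.60)`, `(tau_2, rho_2) = (0.75, -0.50)` and
`beta = (0.5, -0.3, -0.5, 0.3)`; covariates `Z1 ~ Bernoulli(0.4)`,
`Z2 ~ N(0,1)`; auxiliary `A = 1{eps=1} + N(0,1)`.  Under these defaults
the eventual cause probabilities are exact complements
(`F_1(inf;z) + F_2(inf;z) = 1` for every `z`, because the baseline
limits `2/3` and `3/2` are reciprocal and `beta_2 = -beta_1`); the
cause is drawn first and the event time by closed-form inversion of the
conditional subdistribution.  For user-supplied parameters with
`p_1 + p_2 < 1` the remainder is a cured, never-event fraction (logged);
a sum above one is a configuration error.  Visits have Exponential(3)
gaps (one per four months on average) truncated at an administrative
end, default 3 years, which yields ~13.6% right censoring; subjects
whose first visit falls beyond the end are kept as right-censored with
`V = 0`.  The event type of detected events is blanked with probability
`1 - expit(xi0 + 0.5 U - 0.5 Z1 + 0.6 Z2 + xi4 A)`; `xi0 = 0.60,
xi4 = 0` gives a 30% missing rate, and a bisection utility calibrates
`xi0` to any target rate (the 50% scenario) on the model-expected rate
of a large simulated cohort.  Each subject has its own substream
spawned from the master seed, so extending `n` preserves earlier
subjects.

What the generator does *not* emulate: covariate-dependent or
informative examination schedules, truncation, time-varying covariates,
exact event times mixed with intervals, or missingness among censored
subjects.  Passing tests therefore demonstrate correctness of the
estimator under independent, noninformative interval censoring with
MAR types — not robustness to violations of those assumptions.

## Monte Carlo study and problem sizes

`run_scenario` replicates simulate–fit–summarize with counter-based
per-replicate seeds (worker-count invariant under joblib parallelism)
and reports percent bias `100 (mean - truth)/truth`, MCSD, ASE and ECP
per method and coefficient; ASE/ECP require bootstrapping and are off
by default.  The shipped evaluation uses deliberately reduced problem
sizes chosen to keep a single-CPU run short while leaving Monte Carlo
error well below the effects of interest: 100,000 subjects for the
generative-rate checks, 200–500 replicates of `n = 200` for the bias
table (Monte Carlo SE of a percent bias ~2–5 points), a 50 x 50
replicate-by-bootstrap grid for coverage calibration, and 400
replicates of `n = 400` for the double-robustness flip.

The flip diagnostic deserves a note.  With examinations on a *fixed
grid* shared by all subjects, the censoring class and `V` are functions
of `U` alone, so a saturated event-type model on the discrete `(U, Z1)`
cells is exactly correct; pairing it with a deliberately misspecified
intercept-only response model isolates the second leg of double
robustness.  The grid spacing (every 4 months, matching the random
design's mean gap) is chosen fine enough that the sieve's own
finite-sample bias — visible as a few percent when only six distinct
examination times exist — does not confound the diagnostic.

## Known limitations

* The estimator is implemented and exercised for `k = 2`; the data
  layer accepts `k > 2` and the multinomial event-type model is an
  extension point, but the estimator is not routinely tested there.
* No profile-likelihood or closed-form variance: bootstrap only.
* Percent bias is undefined at a zero true coefficient.
* The sieve shows mild magnitude bias (a few percent) at `n = 200`
  when the examination process provides few distinct times; it
  disappears with denser observation or larger `n`.
* MNAR mechanisms and machine-learned nuisance models are out of scope.
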