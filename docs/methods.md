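# Methods

## Model

Incidents are counted on a whole-day grid.  An incident on day *t_i*
raises the probability of further incidents on later days *t_j*
according to an exponential contagion window with mean duration
`T_excite` (days): the excitation probability is the mass of an
Exp(`T_excite`) variable falling within the 24 hours of day *t_j*,

    P(t_j | t_i, T) = e^{-(Δ-1)/T} − e^{-Δ/T},   Δ = t_j − t_i ≥ 1,

which telescopes to 1 over Δ = 1..∞, so `N_secondary` — the branching
ratio multiplying the kernel — is interpretable as the expected number
of secondary incidents directly incited by one incident.  The expected
count on day *t_n* is the baseline plus the excitation pressure of all
earlier events:

    N_exp(t_n) = N0(t_n) + N_secondary · Σ_{t_i < t_n} P(t_n | t_i, T_excite).

Same-day pairs do not excite each other: the kernel's day-Δ integral is
degenerate at Δ = 0, so excitation starts the following day.

Observed daily counts are modelled as Poisson with mean `N_exp(t)`
conditioned on the *observed* history.  Poisson (rather than Bernoulli)
is the minimal count model that permits the multiple same-day incidents
real catalogs contain, and makes the no-contagion null an ordinary
Poisson regression.  The process is stationary only for
`N_secondary < 1` (sub-critical branching), where the long-run mean rate
is `N0 / (1 − N_secondary)`.

## Baselines

`N0(t)` absorbs slow non-contagious variation.  Three forms:

* `constant` — one rate parameter (events/day);
* `linear` — rates at the span start and end, both ≥ 0, interpolated
  (this parametrization keeps the line non-negative without constraints
  on a slope);
* `running_mean` — a Gaussian-kernel weighted running mean of the daily
  counts themselves, standard deviation = `bandwidth_days` (default
  365 d), truncated at 4 sd and renormalized by the in-span kernel mass
  so edges are unbiased; one fitted global scale.  The bandwidth must
  sit far above the excitation scale (a warning fires below 10× ~13 d),
  otherwise the baseline absorbs the contagion signal.  Because the
  running mean is computed from data that include any contagion excess,
  fitted branching ratios under this baseline are conservative (lower
  bounds in spirit).

Optional day-of-week and month-of-year multipliers (mean 1, so they
redistribute rate without changing its level) capture calendar structure
such as weekend or school-year concentration.  They are estimated once
from exposure-adjusted empirical frequencies and held fixed during
likelihood maximization, keeping the fitted space to
(`N_secondary`, `T_excite`, baseline level/trend).

## Fitting

At fixed `T_excite` the day-t mean is linear in the remaining
parameters, so the inner problem is a concave Poisson identity-link GLM;
it is solved by a projected damped Newton iteration with active-set
handling of the bounds (`N_secondary ∈ [0, 5]`, baseline coefficients
≥ 0).  Each iteration costs O(#event-days): only event days enter the
`y log μ` term and the `Σ μ` term reduces to a precomputed column-sum
dot product.  The excitation regressor for a given duration is computed
in O(span) by the recursion `B(t+1) = (B(t)+c_t)·e^{−1/T}`.

The outer 1-D profile over `T_excite` is globalized on the fixed start
grid {1, 2, 4, 7, 14, 30, 60, 120, 365} days (the profile can be
multimodal in T) and the best start is polished by bounded scalar
minimization in log T within the box [0.5, 365] d.  The solver is
deterministic; solutions on a box edge are flagged in the convergence
diagnostics.  Fits require ≥ 10 events and warn below 30.

Confidence intervals are profile-likelihood intervals: endpoints where
the profile log-likelihood (all other parameters re-optimized) drops
χ²₁(0.95)/2 = 1.92 below the maximum, found by bracketing and Brent root
search; the lower `N_secondary` endpoint is clipped at 0 and endpoints
that never cross inside the box are reported at the box edge and
flagged.  Asymmetric intervals are expected and typical.

## Likelihood-ratio test

The null removes both contagion parameters.  `T_excite` exists only
under the alternative and `N_secondary = 0` is a boundary point, so the
χ² reference distribution is not trustworthy (Davies problem).  The
default calibration is a parametric bootstrap: simulate `n_boot`
(default 999) series from the fitted null baseline over the same span
and calendar, refit both models on each replicate with the identical
optimizer settings, and report
`p = (1 + #{Λ* ≥ Λ}) / (n_boot + 1)`.  A χ²(df = 2) p-value is available
for comparability; it is generally conservative here.  A 500-simulation
calibration run in the test suite confirms the bootstrap test holds its
nominal 5% size.

## Synthetic-data generator

`GeneratorSpec` simulates the same process sequentially: per day a
Poisson draw with mean given by the baseline plus the excitation of
already-generated events (strictly earlier days only).  Defaults emulate
an 8-year national catalog of severe firearm incidents: 2922 days from
2006-01-01, constant baseline 0.0422 events/day, `N_secondary = 0.3`,
`T_excite = 13.2` d — a stationary rate of ~0.06/day, i.e. roughly one
incident every ~17 days and ~176 expected events.  Attributes: states
drawn proportionally to population (approximate 2012-era packaged
table) times optional per-state multipliers; coordinates at the state
center with 0.5° Gaussian jitter; victim counts 4 + geometric overshoot
(mean 5), matching a ≥ 4-victims inclusion threshold with a heavy right
tail; firearm and perpetrator-suicide flags Bernoulli(0.76)/(0.46).

What the generator does *not* emulate: reporting or curation biases,
date-transcription errors, within-state geography (events sit near state
centers), severity–contagion interaction (all events excite equally),
and any genuine spatial diffusion.  Passing tests therefore demonstrate
correctness of the estimator and calibration of the tests under the
model's own assumptions — not robustness of conclusions drawn from any
particular curated real-world catalog.

## Clustering and ecology stages

Pairwise inter-event day differences and great-circle distances
(haversine, Earth radius 6371 km) feed a Mantel permutation test:
Pearson (default) or Spearman correlation over unordered pairs, null
distribution from jointly permuting the labels of one matrix, one-sided
for positive association by default (clustering is the alternative of
interest; pairs sharing an event are dependent, which the permutation
scheme respects).  Default 9999 permutations;
`p = (1 + #{r* ≥ r})/(n_perm + 1)`.  Records without coordinates are
dropped from spatial analysis (with a count) but kept for temporal
analysis.

State ecology: with national per-person rate μ = total incidents /
total population, each state's observed count is located by the binomial
CDF `F(k_i | N_i, μ)` (computed via the regularized incomplete beta, so
it is stable at N ~ 10⁷, μ ~ 10⁻⁷).  F near 1 (0) flags incidence above
(below) the national average.  Correlations of F with covariates are
Pearson by default — the critical |r| ≈ 0.28 at α = 0.05 for n = 50
matches the Pearson t-test threshold — with Spearman and a per-capita
rate alternative configurable.  A partial-correlation option
residualizes both variables on a control covariate (typically the
firearm proxy) by simple linear regression.  The firearm-ownership proxy
pools suicide counts over years within state before taking the ratio.

## Numerical and design choices

* Day-of-week/month tests use exposure-weighted expected counts (days of
  each type actually in the span), not flat 1/7 or 1/12, because spans
  rarely contain whole weeks/years.
* The severity comparison uses the pooled-variance two-sided Student t;
  two degenerate equal constant groups return p = 1 by symmetry.
* Likelihood bookkeeping keeps the log-factorial term, so reported
  log-likelihoods are complete Poisson log-likelihoods; a day with an
  event but zero modelled mean yields −∞, reported as such.
* `logL_full ≥ logL_null` is enforced structurally: the null solution is
  a feasible point of the full model, and the full fit falls back to it
  if numerics ever place it lower.
* Bootstrap refits re-estimate everything (calendar weights, running
  mean) from each simulated series, keeping the observed and bootstrap
  statistics exchangeable under the null.
* Test-suite problem sizes: recovery uses 100 replicates of 3000-day
  series at (0.08/day, 0.3, 13 d); the type-I study uses 500 null
  simulations with 199 bootstrap replicates each; the Mantel calibration
  uses 500 label permutations of a ~60-event catalog at 199 permutations
  per test.  These sizes give binomial/KS margins comfortably wider than
  the effects being checked while keeping the suite fast.

## Limitations

* The kernel is purely temporal and unmarked: severity, weapon type and
  media salience do not modulate excitation.
* The running-mean baseline is one reasonable nonparametric choice; a
  different smoother would shift fitted branching ratios somewhat (the
  direction of the bias — toward understating contagion — is known).
* Profile CIs rely on the χ²₁ drop calibration, which is approximate
  near the `N_secondary = 0` boundary; coverage is verified by
  simulation at the default study conditions only.
* Ecological correlations across states cannot support individual-level
  or causal claims.
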