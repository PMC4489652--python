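# selfexcite

Self-exciting contagion analysis of rare-event catalogs — mass killings,
school shootings and similar incident lists — in Python.

Media coverage of a sensational violent event may transiently raise the
probability of similar events in the following days.  `selfexcite` tests
for that signature in an incident catalog by fitting a discrete-day
self-exciting point process: the expected number of events on day
*t<sub>n</sub>* is

```
N_exp(t_n) = N0(t_n) + N_secondary * Σ_{t_i < t_n} P(t_n | t_i, T_excite)
P(t_j | t_i, T) = exp(-(t_j - t_i - 1)/T) - exp(-(t_j - t_i)/T)
```

where `N_secondary` is the branching ratio (mean number of secondary
incidents directly incited by one incident), `T_excite` the mean
contagion duration in days, and `N0(t)` a slowly varying baseline
(constant, linear, or a Gaussian-weighted running mean of the data, with
optional day-of-week/month weights).  Daily counts are Poisson with mean
`N_exp(t)` given the observed history.  Contagion is tested with a
likelihood-ratio statistic against the `N_secondary = 0` null, calibrated
by parametric bootstrap because the duration parameter is unidentified
under the null.

The package also provides the surrounding pipeline: catalog CSV reading
and filtering with calendar/severity descriptive tests, a seeded
synthetic-catalog generator (also the bootstrap engine), Mantel
permutation tests for space–time clustering, and state-level ecological
analysis via the binomial-CDF incidence statistic `F(k_i | N_i, μ)`
correlated with covariates such as the firearm-ownership proxy (state
fraction of suicides by firearm).

## Worked example

```python
import selfexcite as sx

# simulate an 8-year catalog with genuine contagion (defaults:
# baseline 0.0422 events/day, branching ratio 0.3, duration 13.2 d)
catalog, series = sx.simulate_catalog(sx.GeneratorSpec(), seed=1)
fit = sx.fit_contagion(series, "constant", compute_ci=True)
print(f"N_secondary = {fit.params_hat.n_secondary:.3f}  "
      f"95% CI [{fit.ci_n_secondary[0]:.2f}, {fit.ci_n_secondary[1]:.2f}]")
print(f"T_excite    = {fit.params_hat.t_excite:.1f} d  "
      f"95% CI [{fit.ci_t_excite[0]:.1f}, {fit.ci_t_excite[1]:.1f}]")

lrt = sx.lrt_contagion(series, "constant", n_boot=999, seed=2)
print(f"LRT Λ = {lrt.statistic:.2f}, bootstrap p = {lrt.p_value:.4f}")

mantel = sx.time_distance_correlation(catalog, n_perm=9999, seed=3)
print(f"Mantel r = {mantel.statistic:.3f}, p = {mantel.p_value:.3f}")
```

prints

```
N_secondary = 0.283  95% CI [0.11, 0.52]
T_excite    = 12.8 d  95% CI [5.4, 60.2]
LRT Λ = 10.59, bootstrap p = 0.0020
Mantel r = 0.017, p = 0.209
```

The fitted branching ratio recovers the generating value 0.3 (each
incident incites ~0.28 follow-on incidents) and the contagion window the
generating 13.2 days; the bootstrap p-value rejects the no-contagion
null, while the Mantel test correctly finds no space–time clustering —
the generator ties locations to state population, not to event timing.

A `selfexcite` command-line tool exposes the same pipeline
(`simulate`, `describe`, `fit`, `lrt`, `spatial`, `states`); see
`selfexcite --help`.

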