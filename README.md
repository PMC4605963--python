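# bayesmig

Probabilistic projection of net international migration rates and counts
for all countries, using a Bayesian hierarchical AR(1) model on five-year
net migration rates.

The package provides:

- **`bayesmig.data_io`** — dataset containers and CSV I/O for WPP-style
  inputs (per-country rates/counts, populations, age×sex migration
  schedules), with an explicit rate↔count convention
  (`count = rate/1000 × population × period_length`).
- **`bayesmig.model`** — the three-level hierarchical AR(1) model:
  per-country `(mu, phi, sigma2)`, hyperpriors
  `mu_c ~ N(lambda, tau²)`, `phi_c ~ U(0,1)`, `sigma2_c ~ IG(a, b)` with
  `a ~ U(1,10)`, `b|a ~ U(0,100(a−1))`, `lambda ~ U(−100,100)`,
  `tau ~ U(0,100)`; log likelihood, log prior, and exact closed-form full
  conditionals.
- **`bayesmig.mcmc`** — a deterministic Gibbs/slice sampler over those
  conditionals with burn-in, thinning, multiple chains, split-R̂ and ESS
  diagnostics, and posterior CSV round-tripping.
- **`bayesmig.projection`** — joint posterior-predictive trajectory
  simulation to an arbitrary horizon with per-age/sex zero-global-net-
  migration correction (overflow redistributed in proportion to projected
  populations), quantile summaries, and correction-sensitivity measures.
- **`bayesmig.baselines`** — persistence-of-rates, persistence-of-counts,
  and a gravity model (`a·L^α·M^β − b·L^γ·M^δ`, per-country constants fit
  by nonnegative least squares; exponents are required config inputs).
- **`bayesmig.evaluation`** — holdout evaluation (per-lead MAE on the
  rate scale, 80%/95% interval coverage, optional regional breakdown) and
  global trend statistics `u(t)`, `w(t)`, and parity-change fractions.
- **`bayesmig.synthetic`** — ground-truth synthetic worlds drawn from the
  model hierarchy for recovery and calibration experiments.

## CLI

```sh
# generate a synthetic world (rates.csv, schedules.csv, future_pops.csv, truth.csv)
bayesmig simulate --countries 40 --periods 12 --seed 1 --out sim/

# fit the hierarchical model
bayesmig fit --data sim/rates.csv --iterations 12000 --burn-in 2000 \
    --thin 10 --chains 3 --seed 1 --out fit/

# simulate corrected joint trajectories
bayesmig project --posterior fit/posterior.csv --data sim/rates.csv \
    --pops sim/future_pops.csv --schedules sim/schedules.csv \
    --horizon 18 --n-traj 4000 --seed 1 --out proj/

# holdout evaluation (Bayesian or baselines)
bayesmig evaluate --data sim/rates.csv --m 3 --model bayesian --seed 1 --out eval/
bayesmig evaluate --data sim/rates.csv --m 3 --model persistence_rates --out eval2/

# point-forecast baselines
bayesmig baseline --data sim/rates.csv --pops sim/future_pops.csv \
    --model gravity --exponents 0.8 0.2 0.5 0.4 --out base/
```

All randomness flows from `--seed`; identical commands produce
byte-identical outputs.

## Input formats

- Rates/counts CSV: `country_id, period_start, value, population`, one
  row per country and five-year period.  Leading missing periods per
  country are allowed; interior gaps are rejected.
- Schedules CSV: `country_id, age_group, sex, weight`, weights summing to
  1 per country (negative entries allowed — net schedules can change sign
  by age).
- Projected populations CSV: `country_id, period_start, population`.
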