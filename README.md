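# penguinperf

Hierarchical Bayesian analysis of penguin performance against environmental
conditions, local krill biomass, and local krill harvest rates.

## The problem

Low catch limits for forage fisheries are often presumed precautionary for
dependent predators. Around the Antarctic Peninsula, however, krill catches
have concentrated in space and time, so *local* harvest rates
(LHR = stratum-specific catch / stratum-specific krill biomass) can be far
higher than the regional catch limit suggests. This package implements, as
a reusable and tested library, an analysis that asks whether three decades
of standardized penguin monitoring indices (clutch-initiation dates,
foraging-trip durations, fledgling masses, breeding success, cohort
strength, ...) from two South Shetland colonies respond to categorized
drivers: the Oceanic Niño Index (ONI), local krill biomass (LKB), and LHR,
in the Bransfield Strait and Drake Passage strata.

It is aimed at quantitative ecologists and fisheries scientists who want to
re-fit the model to their own monitoring tables, probe its assumptions
(category thresholds, priors, φ grouping), or test the inference machinery
on synthetic data with known truth.

## The model

Missing summer biomass is imputed from a truncated log-normal,

    LKB_ij ~ log-Normal(K_ij, φ²) on [catch_i, 100 Mt],
    K_ij ~ U(0.1·k̄_ij, 10·k̄_ij),  φ ~ U(0.1·s_ij, 10·s_ij),

with (i, j) = stratum × summer-SAM sign and k̄, s from the acoustic
surveys; LHR* = catch / LKB*. Standardized performance p is an exchangeable
ANOVA with sum-to-zero contrasts,

    p ~ N(P, σ²),  P = α + β₁o₁ + β₂o₂ + β₃b + β₄h₁ + β₅h₂,
    α, β ~ N(0, 10⁴),  σ ~ half-Cauchy(ω),  ω ~ U(0, 2),

where the contrast codes categorize ONI at ±0.5 °C, LKB at 1 Mt, and LHR at
0.01 and 0.1. Both components are sampled jointly by an adaptive
Metropolis-within-Gibbs sampler, so imputation uncertainty (including
category flips of LKB*/LHR* across the thresholds) propagates into the
effect estimates. Headline outputs are scenario comparisons: the posterior
(and posterior-predictive) probabilities that expected performance under,
say, the "worst case" (neutral ONI, LKB > 1 Mt, LHR ≥ 0.1) falls below the
"best case" (La Niña, LKB ≤ 1 Mt, LHR ≤ 0.01) or below the long-term mean.

See `docs/methods.md` for assumptions, priors, numerical choices, and
limitations.

## Worked example

Generate a synthetic study with known truth, fit it, and read the scenario
table:

```sh
penguinperf synth --seed 1 --out demo
cat > demo/config.yml <<'YAML'
paths:
  performance: demo/performance.csv
  survey: demo/survey.csv
  catch: demo/catch.csv
  climate: demo/climate.csv
sampler:
  seed: 7
output: demo/results
YAML
penguinperf fit --config demo/config.yml --desk-schedule
```

which logs

```
results in demo/results
```

and writes `analysis_table.csv`, `exclusions.csv`, `draws.csv`,
`diagnostics.json`, `imputations.csv`, `table1.csv`, `fig2_summary.csv`,
and `manifest.json`. The comparison matrix (`table1.csv`, abridged) for
this seed reads:

```
scenario           Best case  Long-term mean  Long-term mean (predictive)
Best case                     0.0000          0.2070
LKB > 1 Mt         0.6947     0.0000          0.2267
0.01 < LHR < 0.10  0.9987     0.2877          0.4563
LHR >= 0.1         0.9740     0.3660          0.4357
Worst case         1.0000     0.9937          0.8027
```

Each cell is the posterior probability that the row scenario's expected
performance is below the column's; the predictive column simulates one new
observation per draw, so residual noise pulls values toward 0.5. Here the
generating truth put strong penalties on neutral ONI and high LHR and
almost none on high LKB, and the fitted probabilities reproduce exactly
that ordering: a marginal biomass increase is barely distinguishable from
the best case (0.69), while the worst case is almost surely worse (1.00)
and a new observation under it falls below the long-term mean with
probability ≈0.80. `diagnostics.json` carries split R-hat, ESS, and
per-block acceptance rates (all core R-hats ≤ 1.09 in this run); the fit
aborts if any core R-hat exceeds 1.1 (`--allow-nonconverged` overrides).

To fit your own data, point `paths:` at CSVs with headers
`site,species,parameter,season,year,value` (performance),
`stratum,season,year,biomass_t` (survey), `stratum,season,year,catch_t`
(catch), and `index,year,month,value` (climate), and optionally override
thresholds, the site→stratum map, φ grouping, and the sampler schedule in
the same YAML. `--paper-schedule` runs the published 3 × (250k adapt,
500k burn-in, 5000 retained) schedule.

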