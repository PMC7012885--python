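# Methods

## The model

`penguinperf` estimates how standardized indices of penguin breeding and
foraging performance respond to three categorized drivers in two Antarctic
Peninsula strata (Bransfield Strait and Drake Passage): the Oceanic Niño
Index (ONI), local krill biomass (LKB, tonnes), and the local harvest rate
(LHR = stratum krill catch / LKB). The model has two coupled components.

**Biomass imputation.** Summer LKB in stratum *i* under summer-SAM sign *j*
is log-normal,

    LKB_ij ~ log-Normal(K_ij, φ²)   truncated to [catch_i, 100 Mt],

so an imputed biomass can never be below the krill actually removed that
season, nor above roughly twice the regional standing-stock estimate.
Survey summaries give uniform priors K_ij ~ U(0.1·k̄_ij, 10·k̄_ij) and
φ ~ U(0.1·s_ij, 10·s_ij), where k̄_ij and s_ij are the mean and SD of
ln LKB over the surveyed summers in cell (i, j). Summers without surveys
get a latent LKB\*, and LHR\* = catch / LKB\*. Winters are never imputed;
winter observations from unsurveyed winters are excluded (and reported).

**Performance ANOVA.** All performance indices are treated as exchangeable
z-scores p, with

    p ~ N(P, σ²),    P = α + β₁o₁ + β₂o₂ + β₃b + β₄h₁ + β₅h₂,

where (o₁, o₂), b, (h₁, h₂) are sum-to-zero contrast codes for the ONI
(≤ −0.5 °C / between / ≥ 0.5 °C), LKB (≤ 1 Mt / > 1 Mt), and LHR (≤ 0.01 /
between / ≥ 0.1) categories. Priors: α, β ~ N(0, 10⁴) (variance;
SD = 100), σ ~ half-Cauchy with scale ω, ω ~ U(0, 2).

The two components share one posterior: each LKB\* feeds the design matrix,
so an LKB\* update can flip the b and h codes of its season-year across the
1 Mt / 0.01 / 0.1 thresholds and re-bin that season's observations. This
carries imputation uncertainty into the effect estimates.

## Interpretation choices where the notation was open

- *Prior variance.* N(0, 1.0×10⁴) is read as a variance (SD 100),
  consistent with the σ² notation of the likelihood.
- *Half-Cauchy scale.* "half-Cauchy(ω²)" is parameterized by scale ω with
  density 2/(πω(1+(σ/ω)²)); a config switch is not provided for the ω²
  reading because the U(0, 2) hyperprior only makes sense on the scale.
- *φ grouping.* The likelihood is written with a single φ while its prior
  is subscripted per (stratum, sign) cell. Default: one φ per cell with
  prior U(0.1·s_ij, 10·s_ij); `phi_grouping="shared"` uses a single φ with
  the pooled log-scale SD.
- *SAM = 0* counts as the positive phase (the categorization must be total;
  exact zeros have probability zero).
- *Imputed summers.* Every summer in the study range without a survey is
  imputed (not only post-2011), configurable via `impute_years`.
- *Cape Shirreff summer indices* use the same stratum as the corresponding
  winter indices (chinstrap → Drake, gentoo → Bransfield); the tracking
  evidence only pins down the winter assignments.
- *Logit boundaries.* Proportions with known trial counts use the
  empirical-logit adjustment (x+0.5)/(n+1); otherwise they are clamped to
  [10⁻³, 1−10⁻³]. Egg volume uses Hoyt's coefficient V = 0.000507·L·W²
  (cm³ from mm), overridable.
- *Standardization* uses the sample (n−1) SD per parameter × species ×
  site group.

## Sampling

A component-wise adaptive random-walk Metropolis (Metropolis-within-Gibbs)
sampler, one block per scalar parameter. σ, φ-block biomasses and each
LKB\* are updated on the log scale with the Jacobian included; LKB\*
proposals are reflected at the truncation bounds in log space. Proposal
scales adapt in batches of 50 toward the 20–50% acceptance band during the
adaptation phase only and are frozen afterwards. The performance likelihood
is evaluated from per-bin sufficient statistics (count, sum, sum of squares
over the 18 predictor bins), making every block O(18) in the number of
observations; an LKB\* update touches only its own season's statistics.
Incrementally updated quantities are refreshed from scratch every 2000
iterations to bound floating-point drift.

Chains are initialized dispersed: α, β ~ N(chain offset, 1), σ, ω ~
U(0.5, 1.5), K and φ jittered around their survey anchors inside the prior
support, LKB\* from its truncated-lognormal prior draw. A non-finite
initial log posterior is an error.

Schedules: the published schedule (3 chains; 250k adaptation, 500k burn-in,
5000 draws retained from every 25th of a further 125k iterations) is
available as `paper_schedule()` / `--paper-schedule`; the default
`desk_schedule()` (3 chains; 5k / 20k / 1000 retained of 5000 thinned by 5)
is sized for interactive work. Split R-hat (rank-normalized) and
autocorrelation ESS are computed via arviz; the pipeline exits non-zero if
any core parameter has R-hat > 1.1 unless `--allow-nonconverged`.

## Scenario summaries

Named scenarios: best case (ONI low, LKB low, LHR low), worst case
(ONI mid, LKB high, LHR high), and marginals that vary one factor from the
best case. For each retained draw, the scenario expectation P follows from
the contrasts; comparison probabilities are Monte-Carlo fractions of draws,
and posterior-predictive probabilities add one simulated observation
N(P, σ²) per draw. The long-term mean is exactly 0 on the standardized
scale, because standardization forces every index's study-period mean to 0.
All cells of the comparison matrix are computed; the predictive column is
reported alongside the posterior one.

## The synthetic-data generator

The generator emulates the monitoring design rather than any particular
data values: split-years 1982–2016; summer surveys 1996–2011 and winter
surveys 2012/2014/2015 only; AR(1) monthly ONI (lag 0.85, innovation SD
0.45 °C) and white-noise monthly SAM (SD 1.2), re-drawn until all three ONI
categories and both SAM signs occur; log-normal biomass per stratum ×
SAM-sign cell (K = 14.5/13.5 ln t in the Bransfield, 14.2/13.2 in the
Drake, for negative/positive SAM; φ = 1.2), spanning ~3 orders of magnitude
(≈7×10⁴–2×10⁷ t); and a two-era catch history (≈34,000 t/yr before 2010,
≈121,000 t/yr after, winter-concentrated in the later era).

Catches are allocated per stratum and season with log-normal noise and then
capped at a fraction of the local standing stock (0.8% in the low-catch
era; 5% in summer and 35% in winter of the high-catch era). The cap encodes
that the fishery can only remove krill it finds locally; it guarantees
catch ≤ biomass and reproduces the observed qualitative pattern — harvest
rates ≥ 0.1 only in recent winters, with a maximum around 0.3 and
pre-2010 rates at or below 0.01.

Twenty indices (4 colonies × 5 parameters) are generated as
z ~ N(P_true, σ_true²) from the true bin of the matched stratum-season-year
and emitted on native scales (day-of-season for clutch initiation, hours
for trip duration, proportions for cohort strength and crèche success,
grams for fledgling mass) so the preprocess transforms are exercised end to
end. Default true effects (β = −0.35, −0.20, −0.05, −0.10, −0.40; σ = 0.9)
put the large penalties on neutral-ONI and high-LHR conditions, matching
the qualitative structure the model is meant to detect, without copying
any estimated values.

What the generator does *not* emulate: survey measurement error around the
latent biomass (surveys report the latent value exactly), serial
correlation in penguin performance across years, site- or species-level
random effects, and observation counts varying by year. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to the additional structure real
monitoring data may contain.

## Coverage estimand

Standardization rescales each index group by its realized sample moments,
so the generating (α, β, σ) correspond on the analysis scale to

    α_eff = mean_g[(α − m_g)/s_g],  β_eff = β·mean_g[1/s_g],
    σ_eff = σ·sqrt(mean_g[1/s_g²]),

with m_g, s_g the sample mean and SD of group g's latent z-scores
(`synthetic.effective_truth`). Credible-interval coverage is assessed
against these values, since the model only ever sees standardized data.

## Problem sizes

A default synthetic study yields 700 index values, of which ≈444 enter the
likelihood (winter observations outside 2012/2014/2015 are excluded as
non-imputable) and ≈38 summers are imputed. The coverage study runs 25
replicates at a reduced schedule (2 chains; 2000 adaptation, 4000 burn-in,
1000 retained of 4000 thinned by 4), which pilot diagnostics showed is
ample for these posteriors (split R-hat ≲ 1.05 on core parameters). The
distributional sampler checks use 10⁵ draws.

## Known limitations

- The likelihood is discontinuous in each LKB\* (category flips), so
  gradient-based samplers are not applicable without smoothing; mixing of
  the rarely-populated mid-LHR contrast (β₄) is the slowest of the blocks.
- α is weakly identified: standardization pins every group mean to zero, so
  the grand mean mostly reflects the imbalance of bin occupancy.
- Catch is treated as exact; biomass survey error beyond the log-normal
  cell variation is not modeled.
- With per-cell φ and few surveyed winters, winter biomass enters only
  through the observed 2012/2014/2015 values; no winter imputation is
  attempted by design.
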