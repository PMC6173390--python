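# Methods

`ssbreform` simulates a national reformulation policy that gradually lowers
the added-sugar content of sugar-sweetened beverages (SSBs), and propagates
the resulting intake change through an individual-level dynamic
energy-balance model to survey-weighted changes in body weight, BMI, and
BMI-category prevalence in an adult population.

## Policy model

**Intake goal and per-individual target.** The policy goal is a mean
added-sugar intake of at most a fraction `goal` (default 10%) of total
energy intake (TEI). Removing SSB sugar also lowers TEI, so the maximum
SSB added sugar compatible with the goal solves

```
goal = (ssb_max + others) / (tei_init + (ssb_max - ssb_init))
ssb_max = [goal (tei_init - ssb_init) - others] / (1 - goal)
```

Individuals at or below the goal are unchanged; individuals above it are
cut to `ssb_max`; individuals whose non-SSB added sugar alone exceeds the
goal have all SSB sugar removed and remain above the goal (a real feature
of the population, not an error: food-side sugar is out of the policy's
reach). The survey-weighted mean of the per-individual reduction
proportions `|delta| / ssb_init` defines the reformulation target, rounded
*down* to a 5% grid (a regulator would not mandate more than the analysis
supports). For non-consumers the proportion is defined as 0, the continuous
extension of `delta = 0`; a consumers-only denominator is available
(`required_proportion(..., denominator="consumers")`) since either
convention is defensible for a zero-inflated exposure.

**Rollout schedules.** The target phases in over `years` (default 10)
annual steps in three shapes: *decreasing* (a constant multiplicative
yearly cut `r1 = 1 - (1 - target)^(1/years)`, so cumulative
`1 - (1 - r1)^j`; absolute decrements shrink), *constant* (the same
fraction of baseline content each year), and *increasing* (the decreasing
decrements in reverse order). All reach the target at the final year. The
increasing schedule is defined operationally by decrement reversal, which
the first/final-year milestones pin down unambiguously. Schedules are
annual step functions (regulation updates once a year); the cumulative
fraction for year *j* applies from day `365(j-1)+1`.

**Compensation.** A fraction `compensation/100` (default 43%) of the gross
caloric cut is regained from other dietary sources, so the net change in
policy year *y* is `-sugar_ssb * Reduction(y) * (1 - compensation/100)`.
Diet composition is treated as constant: the carbohydrate share of the
*net* change is `carb_fraction_of_change` (default 1). This makes full
compensation an exact null — no net energy change, no net carbohydrate
change, zero weight response — which is the behaviour the policy analysis
requires of that boundary. The alternative accounting (compensated
calories strictly non-carbohydrate, so glycogen and fluid shift even at
100% compensation) would leave a residual ~0.1 kg water effect at full
compensation; we rejected it for that reason, and because replacement
calories from mixed foods carry roughly the baseline macronutrient split.

## Body-weight model

An adult energy-partition model with compartments fat `F`, lean tissue
`L`, glycogen `G` (with `hydration_ratio` = 3.7 g bound water per g), and
extracellular fluid (ECF). An energy imbalance `EB` splits between fat and
lean by the Forbes rule `p = C/(C+F)` with `C = 10.4 rho_l/rho_f` kg:

```
rho_f dF/dt = (1-p) EB        rho_l dL/dt = p EB
TEE = K + gamma_f F + gamma_l L + delta_pa BW + TEF + AT
      + eta_f dF/dt + eta_l dL/dt
```

with energy densities `rho_f, rho_l, rho_g` = 9440, 1816, 4180 kcal/kg,
tissue expenditure slopes `gamma_f, gamma_l` = 3.2, 22 kcal/kg/d,
synthesis/turnover costs `eta_f, eta_l` = 180, 230 kcal/kg, thermic effect
`TEF = 0.10 dEI`, and adaptive thermogenesis `AT` relaxing toward
`0.14 dEI` with a 14-day time constant — the canonical published constants
of this model family, all overridable through `ModelParams`. Glycogen
follows carbohydrate intake with quadratic feedback
(`dG/dt = (CI - CI_b (G/G_b)^2)/rho_g`, baseline store 0.5 kg at a
baseline carbohydrate share of 55% of TEI); ECF relaxes toward an offset
proportional to the relative carbohydrate change. Sodium intake is
unchanged by a sugar reformulation, so the sodium–fluid channel is inert.
The glycogen/ECF sub-model can be disabled (`glycogen_enabled=False`) to
isolate the two-compartment core.

`delta_pa` (7 kcal/kg/d) is a sedentary-to-light physical-activity slope
on total body weight; with the tissue slopes it sets the feedback strength
`dTEE/dBW ≈ 18 kcal/d per kg` along the Forbes path, i.e. a weight-response
time constant of roughly one year — which is why results are read two
years after the rollout ends (horizon 12 years for a 10-year rollout) and
why the three rollout shapes have converged by then.

**Initialization and calibration.** Baseline fat mass uses the Deurenberg
anthropometric regression (`%fat = 1.20 BMI + 0.23 age - 10.8 male - 5.4`),
clamped to 5–60% of body weight with a warning; ECF starts at 23.5% of
body weight, and lean tissue takes the remainder. Each individual is
calibrated to steady state: the offset `K` is solved in closed form so
that expenditure equals reported intake exactly at the baseline state
(residual 0 to machine precision). Because 24-h recalls misreport intake,
`K` can be negative for low reporters; it is a residual offset, not a
physiological quantity, and the simulation remains well-behaved. The
`±3 SD of ln(TEI/TER)` exclusion removes the extreme misreporters first;
the reference requirement TER defaults to the model's own baseline
expenditure with a population-level offset (`k_default` = 500 kcal/d),
keeping the filter self-consistent with the simulation, with an IOM
estimated-energy-requirement variant (`ter_model="iom"`) as an external
alternative. The exact requirement equation behind the published filter is
not recoverable from the text, so it is a config switch rather than a
guess.

**Integration.** Fixed-step classical Runge–Kutta at 1-day steps,
vectorized across the population, with steps aligned to policy-year
boundaries so the piecewise-constant forcing is exact; halving the step
moves 12-year weights by well under 1e-3 kg. A scipy LSODA path is
available for single individuals as a cross-check. Non-finite or
non-physical compartments abort with the offending record ids. Energy
conservation (`rho_f dF + rho_l dL + rho_g dG = ∫(intake - expenditure)`)
is tracked through the same quadrature and asserted in tests. Whether the
published analysis stepped reductions annually or continuously is not
stated; annual steps are used, and by the 12-year horizon the distinction
is immaterial (the schedules agree there to < 0.02 kg).

## Survey aggregation

Estimates are weighted ratio means. BMI categories use WHO cut-points with
underweight collapsed into normal (< 25 / 25–30 / ≥ 30, half-open).
Relative prevalence changes divide the pp change by the baseline
prevalence; projected case counts multiply the pp change by an external
adult-population scalar (documented default 90 M — projections are an
input, never fetched). Design-based uncertainty comes from a stratified
clustered bootstrap over PSUs (default 500 replicates, seeded) or Taylor
linearization; the published analysis's interval method is not described,
so both standard options are exposed and neither is asserted as "the"
method. Intervals reflect sampling error only — the weight model is
deterministic and contributes no parametric uncertainty.

## Synthetic population

The generator emulates an adult 24-h-recall analytic sample: ~3,005
records expanding to ~64.9 M adults; overall means 244.9 kcal/d added
sugar (12.6% TEI) and 101.1 kcal/d from SSBs (5.1% TEI); ~51.8% SSB
consumers; baseline BMI-category prevalences 30.4/38.7/30.9%; and
multiplicative sex, age-group, and SES gradients taken from the published
marginal means. Because the three demographic margins are drawn
independently and the per-margin factors are normalized to weighted mean
1, the generated marginal means reproduce the configured ones by
construction.

Within cells, TEI is log-normal (sigma 0.35) and the two added-sugar
sources are separate log-normal components — non-SSB sugar (sigma 0.70)
and zero-inflated SSB sugar (sigma 0.75 among consumers) — with
dispersions set so the implied sampling variability of the sample means
matches the published confidence intervals (a single 24-h recall has a CV
near 1 for added sugar). Drawing the sources separately, rather than
splitting a total, makes heavy total-sugar intakes predominantly
SSB-driven, as in recall data; a consequence is that the consumers-only
required-reduction proportion comes out near 0.55 on default populations,
the same order as the deposited sample's statistic. Per-cell consumer
shares are proportional to the cell's SSB-to-total-sugar ratio and
normalized to the configured overall share; the consumer-conditional mean
is back-solved so cell SSB means are exact in expectation. Totals are
capped at 85% of TEI (scaling both sources) to keep recalls physically
possible. BMI is log-normal (mu 3.3113, sigma 0.1802 — the two-category
cut-points then give the configured prevalences), linked to the intake
deviate by a weak rank correlation (0.1). Records spread over 30 strata x
3 PSUs with a between-PSU intraclass correlation of 0.02 on the intake
scale, and survey weights are log-normal (sigma 0.5) normalized to the
target expansion.

What the generator does **not** emulate: the real sampling frame and
nonresponse adjustment, item-level recalls, seasonality, within-person
day-to-day variance, any diet–BMI confounding beyond the weak rank link,
and correlation between SES and anthropometry. Passing tests therefore
show that the *pipeline arithmetic and model dynamics* are right under
realistic marginals, not that the published point estimates are recovered
— that requires the deposited survey dataset, and the corresponding
integration test runs only when such a file is supplied locally.

## Problem sizes and numerical choices

Default runs use the full 3,005-record sample (a 12-year daily simulation
of the whole population takes a few seconds); simulation-heavy tests use
seeded populations of 120–400 records and 5x5 sensitivity grids, sizes at
which every asserted property is already sharply resolved. Tolerances:
steady-state drift < 0.01 kg over 12 years; step-halving agreement
< 1e-3 kg; energy conservation to 1e-4 kcal; schedule identities to 1e-12;
the long-run step response matches an independent root-finding oracle on
the Forbes curve within 0.05 kg plus the residual transient. Ties and
degenerate inputs: zero-dispersion log-ratios exclude no one under the
±3 SD rule; non-consumers get proportion 0; a zero target means no policy
(and a None target is resolved from the data at fit time); target 1.0
(full removal) is admitted for sensitivity grids, where the decreasing
schedule degenerates to a single first-year step.

## Known limitations

- Steady-state baseline: secular weight trends, aging, and activity
  changes over the 12 simulated years are excluded by assumption.
- Compensation is a single population-wide constant; heterogeneous or
  beverage-specific substitution is not modeled.
- No child/adolescent growth energetics; adults (age ≥ 20) only.
- Confidence intervals carry no weight-model parameter uncertainty.
- The fat-mass regression is an anthropometric approximation; individual
  body-composition data would override it.
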