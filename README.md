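# migmort

Mortality differences between internal migrants and non-migrants,
analysed the way register-based studies do it — but on synthetic register
data, because the real registers such studies use cannot be shared.

The scientific question: do people who leave their region of birth
("leavers") and people who leave but move back ("returnees") die at
different rates from those who never leave ("stayers")? Comparing these
groups honestly requires solving a chain of methodological problems:
residence is only observed at scattered census years before becoming
annual, so ages at migration are left- and interval-censored; mortality
differences vary strongly by age, so constant-ratio models mislead; and a
difference in life expectancy is only interpretable once decomposed into
the ages and causes of death that produce it. `migmort` implements that
full chain as a reusable, tested pipeline:

1. **Synthetic register** (`migmort.simulate`) — an annual-step
   microsimulation of residence and death histories for 21 regions,
   1970–2018, with mortality
   `log m = baseline(age) + β_region + β_year + β_status + s_status(age)`
   and an observation scheme (censuses 1970/75/80/85, annual 1987–2018)
   that reproduces the censoring patterns of real registers.
2. **History building** (`migmort.histories`) — stayer/leaver/returnee
   classification (leavers banded by age at first migration, returnees by
   age at return), aggregation of deaths `D` and person-years `E` by
   year × 3-year age group × sex × birth region × status, structural-zero
   handling, and proportional redistribution of ill-defined causes.
3. **Censored-age imputation** (`migmort.censoring`) — interval-censored
   maximum likelihood for a piecewise-constant age-at-migration hazard,
   stratified by sex and cohort, with truncated-to-bounds imputation.
4. **Mortality model** (`migmort.gam`) — a negative-binomial GAM of cell
   death counts: `D ~ NegBin(m·E, θ)`, one penalised 10-spline smooth age
   effect per status constrained to sum to zero, REML smoothing selection
   (Fellner–Schall updates) and profiled overdispersion θ.
5. **Marginal rates and ratios** (`migmort.marginal`) — average marginal
   age-specific rates (averaged over all region × year combinations) with
   90% simulation bands; rate ratios with stayers in the numerator, so
   values above 1 mean movers die less.
6. **Life tables** (`migmort.lifetable`) — partial life tables for ages
   20–95 and temporary life expectancies, with mover-vs-stayer gaps in
   months and in percent.
7. **Decomposition** (`migmort.decompose`) — line-integral (Horiuchi)
   decomposition of expectancy gaps into additive age × cause
   contributions, cross-checked against exhaustive stepwise replacement.

`docs/methods.md` describes the models, defaults and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
60,000-person synthetic register (shared config in `analysis/config.yaml`,
artifacts under `results/study/`). For instance:

```bash
python analysis/01_simulate_register.py
python analysis/03_impute_migration_ages.py
python analysis/06_life_expectancy_gaps.py
```

prints, among other things:

```
simulated 60,000 individuals, 32% die during follow-up
final latent status shares (emulated register: ~57% stayers, ~35% leavers, ~9% returnees):
  stayer    53.8%
  leaver    34.0%
  returnee  12.2%

25,740 movers; 35% exactly placed, 45% left-censored to age 0
KS(imputed, true age at first migration) = 0.0061

[m] leaver    vs stayer, ages 20-95:  +10.6 months (+1.5% of stayers' 59.9y)
[m] returnee  vs stayer, ages 20-95:  +80.3 months (+11.2% of stayers' 59.9y)
```

Reading the output: the imputation reconstructs the age-at-first-migration
distribution to a Kolmogorov–Smirnov distance of 0.006 despite 45% of
movers being left-censored; and in this synthetic register the fitted
pipeline turns the generator's built-in mover advantages into positive
temporary-life-expectancy gaps. The synthetic gaps are larger than what a
real register would show, because classifying people by their *final*
status conditions returnees on having survived to their return — a
selection effect of the design that the banding and structural-zero rules
limit but do not remove, and which the validation experiments therefore
measure in selection-free configurations (see `docs/methods.md`).

The same pipeline is scriptable: `migmort run-all --config analysis/config.yaml
--out results/study`, or stage by stage (`simulate`, `build-table`, `impute`,
`fit`, `marginalize`, `lifetable`, `decompose`, `report`).

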