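# Methods

`migmort` analyses mortality differences between internal migrants and
non-migrants on register-style data. Because the registers this kind of
study uses are confidential, the package ships its own synthetic register
generator with the same statistical structure — observation scheme,
censoring patterns, status-structured mortality — and every downstream
component (classification, imputation, modelling, life tables,
decomposition) is validated by recovering what the generator put in.

## The synthetic register

`simulate_population` runs an annual-step microsimulation. Each person has
a sex, a birth year and one of `n_regions` (default 21) birth regions.
Within a calendar year a person first moves (out of the birth region with an
age-dependent hazard; back to it with a return hazard; onward between
non-birth regions with a small hazard), then faces a death draw; the
year-end region is what the register records on December 31st. Migration
operates from birth, but the death draw is active only inside the follow-up
window (default 1970–2018), so cohorts born earlier enter follow-up alive —
the source of left-censored migration ages once observation is restricted.

The death draw uses annual probability `1 − exp(−rate)` with

    log rate = baseline(age) + region_effect[birth region] + year_effect[year]
               + status_effect(current latent status, age)

mirroring the mortality model fitted downstream. Defaults: Gompertz
baseline `log(9e-5) + 0.077·age` (adult rates of roughly 4e-4 at age 20 and
2e-2 at 70); deterministic sum-to-zero region offsets (amplitude 0.12) and a
linear sum-to-zero period trend (−0.012/year, mortality improvement);
constant mover advantages (leaver −0.15, returnee −0.30 on the log scale)
with an optional age-interaction hook. Migration hazards default to
0.007/0.030/0.005/0.002 per year on ages 0–16/17–29/30–59/60+, with return
hazard 0.009; over the default cohorts (1905–1998) this yields roughly 57%
stayers, 35% leavers and 8% returnees, the composition the generator is
meant to emulate. Causes of death are drawn from age-band mixes (external
and alcohol-related causes dominating young-adult deaths, circulatory
disease and neoplasms older ones, dementia the oldest), and a random 2.1%
of deaths are relabelled ill-defined, without structure.

`apply_observation_scheme` masks residence to the observed years — by
default the census years 1970/1975/1980/1985 and annual years 1987–2018 —
while retaining the full paths and true event ages in a ground-truth
sidecar that only test harnesses read. Conventions the data do not pin
down are explicit options: the dying person's final-year residence is
recorded (`"snapshot"`, default) or dropped (`"drop"`), and the death year
contributes 0.5 person-years of exposure by default.

What the generator does *not* emulate: realistic geography or region
sizes, emigration, within-region moves, household structure, or
socioeconomic covariates. Passing tests therefore demonstrate that the
estimation machinery recovers known structure under the study's observation
scheme — not that any substantive conclusion transfers to real registers.

## Classification and exposure

A person is a **stayer** if never observed outside the birth region, a
**leaver** if the last relevant observation (end of follow-up or year of
death) is outside it, and a **returnee** otherwise. Leavers are banded by
age at first out-migration (<17, 17–29, 30–59, 60+), returnees by age at
return (<30, 30–59, 60+). A person's entire exposure is attributed to
their final status; the time-varying alternative is out of scope. This
choice has a consequence the validation experiments must respect: mover
groups are conditioned on surviving to their migration events, so even with
identical underlying rates the classification itself produces apparent
mover advantages. The structural-domain rule removes the part of this that
is exact: person-years and deaths below a band's entry age (a returnee
banded 60+ cannot die at 50 — they returned at 60) are excluded from the
exposure table, as is exposure above age 77 for returnees before 30, whose
oldest members cannot exceed that age under the observation window.

Deaths and person-years aggregate by calendar year × 3-year age group
(20–22, …, 92–94; midpoints 21.5, …, 93.5) × sex × birth region × status.
Ill-defined deaths are reassigned proportionally to the six named cause
groups within 5-year period × 5-year age group × sex strata; strata with no
named-cause deaths fall back to doubled-width windows and then the sex
margin, with a warning. Totals are conserved exactly per stratum.

## Censored migration ages

Between censuses a move can only be placed in a 5-year window, and moves
before 1970 are left-censored to `[0, first observed age)`. Bounds use the
convention `[last origin age + 1, first destination age + 1)`: with annual
observation the interval has width 1 and is treated as exact. The imputation
model is a piecewise-constant hazard on ages 0–16/17–29/30–59/60+,
estimated by maximum likelihood from interval-censored contributions
`S(low) − S(high)` plus right-censored contributions `S(age)` from people
never observed to move. The right-censored terms matter: without them the
likelihood targets the hazard conditioned on migrating, which distorts the
within-interval shape used for imputation. Strata are sex × birth-cohort
band (pre-1940, 1940–59, 1960–79, 1980+); a stratum is only fit on its own
when every hazard band below 60 contains exactly-placed events, because old
cohorts have no exactly observed early-life moves and their young-age
hazard is unidentified — such strata use the pooled fit. Imputation draws
from the fitted distribution truncated to each record's bounds
(inverse-CDF, seeded, single draw by default; multiple-imputation variance
propagation is deliberately out of scope), with a counted midpoint fallback
for bounds carrying no model mass.

Known limitation: a left-censored mover observed *outside* in 1970 is, all
else equal, a later mover than plain truncation implies (early movers are
more likely to have already returned). The imputation ignores this
second-order tilt; under the default conditions the Kolmogorov–Smirnov
distance between imputed and true age distributions is ≈ 0.004 at
n = 50,000, so the approximation is comfortably adequate there.

## The mortality model

Cell death counts are modelled, separately by sex and cause, as negative
binomial with mean `m·E` and overdispersion θ,

    log m = b_region + b_year + b_status + s_status(x),

with `x` the age-group midpoint and `E` the person-years offset. Each
status's smooth `s` is a linear combination of 10 cubic B-splines with an
exact second-derivative penalty, reparameterised so that it sums to zero
over the status's observed midpoints (the status intercept carries the
level). Calendar year enters as categorical coefficients by default; a
penalised year smooth is a configuration option. Cause-specific fits first
restrict ages to the contiguous hull of groups holding at least 0.5% of the
cause's deaths or at least 1000 deaths.

Fitting is penalised IRLS. Smoothing parameters maximise the
Laplace-approximate REML criterion via extended Fellner–Schall
multiplicative updates (each iteration refits, then scales every λ by
`[rank/λ − tr(A⁻¹S)] / β'Sβ`), which converges in a few dozen refits even
with eight smooths; GCV and fixed-λ are options (fixed-λ makes
reference-coding invariance exact, which the tests exploit). θ is profiled
by bounded scalar likelihood maximisation, alternating with the smoothing
updates until it stabilises. Convergence of the inner loop is a relative
deviance change below 1e-8 (cap 200 iterations) with step halving; the
coefficient covariance is the inverse penalised information, and
non-converged fits are flagged and refused downstream.

Numerical guards: linear predictors are clipped to ±30 (a rate of e³⁰ per
person-year is already unphysical), IRLS weights floored at 1e-10, Cholesky
failures fall back to jittered or eigendecomposed factors, and rank
deficiency after constraint absorption raises with the aliased columns
named. Degenerate strata (a status with zero deaths everywhere) estimate a
rate near zero with an enormous variance — statistically honest, but
downstream ratio summaries for such groups are Monte-Carlo noise, which is
why sparse mover bands are excluded from the degenerate-limit validation.

## Marginal rates, ratios, life tables, decomposition

Reported age-specific rates are average marginal effects: the predicted
rate averaged on the rate scale over every (region, year) combination in
the fitted support, equally weighted ("all combinations"; exposure
weighting is an option). Uncertainty comes from 1000 multivariate-normal
coefficient draws; bands are 5th/95th percentiles, so intervals are
posterior-simulation bands, not delta-method intervals. Rate ratios put the
stayers' rate in the numerator — values above 1 mean movers die less — and
are computed draw-wise before taking percentiles.

Partial life tables on ages 20–95 use `nqx = n·nmx / (1 + (n − nax)·nmx)`
with `nax = n/2` (adequate at adult ages), radix 100 000, truncation at 95
(no open interval). Temporary life expectancy between a and b is
`Σ nLx / l(a)`. Gaps versus stayers are reported in months and as a
percentage of the stayers' expectancy; comparisons for banded statuses
start at the band's entry age and the returnee-<30 comparison ends at 77 —
no rates are invented for structurally empty ages.

The expectancy gap between two cause-specific rate schedules is decomposed
by the line-integral method: rates move along the straight line between the
two schedules, and each cell's contribution is its total change times the
midpoint-rule integral (default 1000 steps) of the functional's partial
derivative, obtained by central finite differences (relative step 1e-6).
Because causes add to the all-cause rate, the derivative with respect to
any cause in an age group equals the derivative with respect to that
group's total rate, which makes the computation a batch of perturbed life
tables per step. Contributions sum to the exact gap up to quadrature error
(≪ 1e-6 years at 1000 steps on smooth schedules), negate when the pair is
swapped, and collapse consistently when causes are merged. The exhaustive
stepwise-replacement average over all cell orders is implemented as a test
oracle only.

## Validation experiments and problem sizes

`migmort.validation` packages the recovery experiments the tests and the
acceptance script run: status-effect recovery at n = 200 000 with a known
stayer/mover log ratio of log 2 (measured at a mid-adult age against the
draw-based Monte-Carlo standard error), 90% interval coverage over 50
replicates at n = 6 000, imputation KS at n = 50 000 under the default
scheme, and a null-effect run at n = 30 000. The recovery and null
scenarios complete all migration before age 20 with no returns: with later
or return migration, final-status attribution mixes pre-move person-time
into mover bands and conditions returnees on surviving to return, so a
single "true ratio" does not exist — a property of the design the package
reproduces rather than a bug, and the reason those experiments pin the
selection-free configuration. The sizes above keep each experiment in the
seconds-to-a-couple-of-minutes range while leaving Monte-Carlo error well
inside the asserted tolerances.

## Pipeline

`migmort.pipeline.run` executes simulate → classify/impute → aggregate →
fit → marginalise → life tables → decompose → report into a run directory
with a JSON manifest (config hash, seed, stage log). Artifacts are CSV
throughout; model bundles are `npz` + JSON and reload without refitting.
Re-running a completed stage with an unchanged config is a no-op, and
identical config + seed gives byte-identical numeric artifacts. The
`migmort` CLI exposes each stage (`simulate`, `build-table`, `impute`,
`fit`, `marginalize`, `lifetable`, `decompose`, `report`, `run-all`) as a
thin wrapper with `--config/--seed/--out`. The headline pipeline compares
coarse statuses (stayer/leaver/returnee); `status_detail: bands` switches
to the age-at-migration analysis.
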