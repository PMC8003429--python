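# Methods

## Model overview

`wlharm` measures the externality of a single organ allocation on a liver
transplant waiting list. The list is divided into four non-interacting
strata — cirrhotic candidates with MELD ≤ 20, 21–30, > 30, and HCC
candidates — each a cohort with four compartments: waiting, alive
post-transplant, dead pre-transplant, dead post-transplant. Compartment
counts are expected values, so the model is linear in the initial counts
and each stratum is simulated as a unit cohort and scaled.

Cycles are one day; the horizon is 1826 days (5 × 365.25, rounded). Each
day, waiting patients die/drop out with probability `dp_death` and are
transplanted with `dp_transplant`; post-transplant patients die with
`dp_post_lt_death`. Intention-to-treat life expectancy is the sum over
days of the waiting plus post-transplant-alive mass, divided by 30.4375
days/month. Compartment mass is conserved to 1e−9 over the full horizon
(assertion-checked).

### Daily probabilities (DEALE)

Survival summaries are converted by the declining exponential
approximation of life expectancy: a survival fraction S at t months implies
a constant daily probability `dp = 1 − exp(ln S / (t × 30.4375))`, so that
`(1 − dp)^(t×30.4375) = S` exactly. Medians enter with S = 0.5;
post-transplant mortality is calibrated to the 5-year (60-month) survival.
The month length is fixed at 365.25 / 12 = 30.4375 days everywhere so that
the DEALE conversion, the horizon and all month↔day arithmetic share one
constant.

### The allocation externality

When one organ is allocated, the remaining list waits one organ
inter-arrival interval, `delay = 365 / (organs_per_year × (1 − d))` days,
where d is the fractional decrease in organ supply (d = 0: usual
availability; at 36 organs/year the interval is ≈ 10 days, ≈ 20 days when
supply halves). The model runs twice: undisturbed, and with the transplant
channel closed for `delay` days (death continues; transplant probabilities
are unchanged afterwards). Fractional delays pro-rate the transplant
probability of the boundary day. Two aggregates over the harmed cohort are
reported:

* harm (life-months) = Σ_g n_g × (LE_undisturbed,g − LE_suspended,g)
* extra death risk (percentage points) = 100 × Σ_g n_g ×
  (P_death,suspended,g − P_death,undisturbed,g)

### The harmed cohort

Which patients count as "the others" is a genuine structural choice. The
package's default is the three cirrhotic MELD strata, sized
`wl_size × wl_fraction`: the allocated candidate is an HCC patient served
by the HCC allocation pathway, and the HCC stratum is excluded from the
harm aggregation. This reconstruction reproduces the reference Italian
result for the baseline extra death risk (reported 42.7 %; this model
gives 42.2 %) and keeps every headline quantity within ~15 % of its
reference value; the inclusive alternative (all strata, one candidate
removed from the HCC stratum, available as
`harmed_cohort="all_minus_candidate"`) overshoots the reference risk by
~33 % (56.6 %). The exclusive default is therefore used throughout, with
the caveat that under it the HCC stratum's own medians cannot influence
the harm (see Limitations).

### Packaged defaults

Italian national-average centre, 2012–2018 listing period
(`profiles/../data/italy_2012_2018.yaml`):

| parameter | MELD ≤ 20 | MELD 21–30 | MELD > 30 | HCC |
|---|---|---|---|---|
| median WL survival (months) | 29.5 | 6.7 | 0.9 | 20.7 |
| median time to transplant (months) | 12.8 | 4.4 | 0.7 | 9.5 |
| 5-year post-LT survival | 0.83 | 0.81 | 0.76 | 0.81 |
| share of the list | 0.37 | 0.13 | 0.04 | 0.46 |

with 58 candidates and 49 organs/year. All percentages are stored as
fractions internally; config files accept either unit via explicit
`*_pct` keys. Uncertainty ranges for every parameter (used by the Monte
Carlo module) are packaged alongside, with the organ decrease sampled
uniformly on [0, 0.8) by default — covering the deepest supply reductions
reported during the pandemic.

## Benefit, net benefit, thresholds

Five-year transplant benefit (life-months): `1.14·MELD − 0.46·log10(AFP) +
0.52` for T2 HCC and `0.89·MELD − 3.59` for non-HCC candidates, taken as
given from the published derivation; MELD is clamped to the clinical
[6, 40] range. The AFP logarithm is base 10: with it, moving AFP from 10
to 1000 ng/mL shifts the benefit by 0.92 life-months ≈ 0.8 MELD units,
matching the reported "< 1 MELD unit" sensitivity (natural log would give
1.9 units). Note the reference analysis described the threshold as
*decreasing* to 14 at AFP 1000 ng/mL, while the formula's sign makes
higher AFP *raise* the threshold; the formula is implemented as printed
and the direction discrepancy is simply flagged here.

The MELD threshold for a harm h is the largest integer MELD in [6, 40]
whose benefit is ≤ h (candidates must exceed it); 5 is returned when even
MELD 6 outweighs h ("all eligible"), and `None` when not even MELD 40 does
("none eligible"). Threshold and net-benefit curves across shortage
scenarios are thin tabulations over `compute_harm`.

## Monte Carlo metamodel

Each of n draws samples every profile parameter and the organ decrease
independently and uniformly within its range; stratum shares are
renormalized to sum to one after sampling. Reported "MELD-mix" variation
is realized through the stratum shares and stratum medians — the cohort
model carries no individual MELD scores. Post-transplant survivals are
sampled but, matching the published covariate set, omitted from the
default regressor list. The harm engine runs vectorized over all draws
(~2.5 s per 10,000 draws on one core).

The metamodel is ordinary least squares of ln(harm) — the response is
log-transformed because the published summary equation is an exponential
of a linear predictor — on 14 covariates: organ decrease in percentage
points, organs-to-list ratio, list size, shares with MELD > 20, MELD > 30
and HCC, and the eight stratum medians in months. Only this unit mix makes
the published coefficient magnitudes dimensionally coherent. p-values are
two-sided t-tests with n − k − 1 degrees of freedom, no multiplicity
adjustment. The published four-covariate simplified equation
`exp(3.07 + 0.03·Δ% + 1.18·f_{MELD>20} − 0.88·f_HCC − 1.03·organs/list)`
is provided as a standalone evaluator with overridable coefficients.

## Synthetic registry

The generator emulates the statistical structure the model assumes:
stratum membership ~ categorical(shares); entry uniform on an accrual
window; latent exponential times to death/dropout and to transplant with
the configured medians, competing; administrative censoring; exponential
post-transplant mortality calibrated to the 5-year survival. Event days
are integers (ceiling of continuous times). All draws flow from a single
seeded generator, so registries are reproducible bit-for-bit.

Exponential (constant-hazard) exit times are an internal design choice —
they are exactly the structure the DEALE conversion assumes — not an
empirical claim about real waiting lists. Because transplant assignment
within a stratum is independent of the death process by construction,
plain Kaplan–Meier estimates are unbiased here; the dependent-censoring
(IPCW-style) corrections a real registry needs are deliberately out of
scope. The generator also omits covariate structure (age, sex, etiology,
blood group), MELD migration over time, and re-listing; passing
parameter-recovery tests therefore validates the estimation pipeline, not
the realism of any particular national registry.

Profile re-estimation uses per-stratum Kaplan–Meier medians (lifelines)
with two refinements for day-granular data: the survival curve is
interpolated linearly across the step that crosses 0.5 (only once the
curve has already begun to fall — a first drop straight through 0.5 is a
genuine mass point and keeps the step median), and half a day is
subtracted to undo the ceiling of event days. List size is estimated as
the mean daily census over the final year of follow-up, organ supply as
the transplant count over that year.

## Validation oracles

* DEALE round-trip: `(1 − dp)^(t×30.4375)` recovers S to 1e−12.
* Death-only cohorts match the geometric-series life expectancy to 0.1 %.
* The cohort recursion is checked against an independent per-patient
  microsimulation: exit days are simulated as geometric draws; conditional
  on the exit day, the exit type and the truncated-geometric
  post-transplant survival are integrated analytically
  (Rao–Blackwellization), leaving a Monte Carlo standard error of ~0.1 %
  at 100,000 patients against a 0.5 % acceptance band.
* An exact log-linear response is recovered by the metamodel to 1e−8.

## Problem sizes and seeds

Default test/validation sizes: 10,000 Monte Carlo draws × 5 seeds (1–5)
for the metamodel sign-stability check; 10 registries (seeds 0–9) of 5,000
patients with a 1-year accrual window and 15-year administrative censoring
for parameter recovery (target: stratum medians within 5 % on the 10-seed
average); 100,000 patients per stratum for the microsimulation check. All
seeds were fixed when the checks were designed.

## Numerical choices

* Suspension boundary days pro-rate `dp_transplant` linearly.
* Compartments are monitored for negativity (tolerance 1e−15) and mass
  conservation (1e−9/cycle) when checking is enabled.
* `dp_death + dp_transplant < 1` is enforced for profile-derived rates;
  the low-level engine accepts the degenerate sum of exactly 1.
* Thresholds are computed on integer MELD; curves accept real MELD.
* Median-not-reached in profile re-estimation raises a named error rather
  than returning infinity; degenerate post-transplant data with no deaths
  yield a 5-year survival of exactly 1.

## Known limitations

* **Sub-proportional shortage response.** The suspension interval scales
  as 1/(1 − d), but the harm saturates slightly below that scaling because
  the sickest stratum (median survival 0.9 months, dp_death ≈ 0.025/day)
  partly dies off within longer suspensions: harm(0.5)/harm(0) ≈ 1.89 and
  risk(0.5)/risk(0) ≈ 1.90 rather than the idealized 2.0, and the harm
  curve falls ~5 % below harm(0)/(1 − d) by d ≈ 0.5 and ~9 % by d ≈ 0.65.
  Any faithful daily-cycle cohort model shows this; an exact doubling
  would require linearizing the death process over the suspension.
* **HCC medians are inert under the default harmed cohort.** With the HCC
  stratum excluded from harm aggregation, its median survival and time to
  transplant cannot influence the harm; their metamodel coefficients are
  statistically null (|t| < 2) and their signs are sampling noise, unlike
  the reference coefficient table where both are significantly negative.
  The HCC *share* still matters strongly (it sizes the cirrhotic cohort).
* The reference coefficient ranking (organs-to-list ratio and HCC share as
  the two strongest negative covariates) is not reproduced: under this
  engine the sickest stratum's medians carry more weight.
* No individual queue positions, allocation points, donor–recipient
  matching, MELD trajectories, re-listing, or post-pandemic excess
  post-transplant mortality; strata are static over follow-up.
* A 10-year benefit horizon (which would be more permissive) is not
  implemented; the five-year horizon matches the acute-crisis framing.
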