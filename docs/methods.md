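# Methods

## Scope and design

`ckdsim` is a discrete-time (annual-cycle), individual-level
state-transition model of chronic kidney disease (CKD) in a screened
high-risk cohort. It is a closed-cohort model by default: the simulation
follows the individuals present at baseline; no births or entries occur,
and incident CKD among AT_RISK members is off (`p_ckd_incidence = 0`)
unless configured otherwise.

Six states: `AT_RISK`, `CKD_UNDETECTED`, `CKD_DIAGNOSED`, `CKD_TREATED`,
`ESRD`, `DEAD`. CKD stages I–IV are deliberately lumped: the utility
(0.81) and outpatient cost (4,159 yuan/yr) inputs are single figures for
stages I–IV, so finer staging would add parameters with no data behind
them. Detection without treatment changes accounting only; the
`CKD_UNDETECTED` and `CKD_DIAGNOSED` rows of the transition matrix are
identical.

## Transition model

All transitions are annual probabilities over the ordered state set; rows
sum to 1 to within 1e−12 and `DEAD` is absorbing.

| parameter | default | meaning |
|---|---|---|
| `r_gen_mort` | 0.00887 /person-yr | general-population all-cause mortality rate |
| `p_esrd_mort` | 0.0338 | annual death probability in ESRD |
| `hr_ckd_mort` | 1.63 (1.50–1.77) | death HR, pre-end-stage CKD vs general population |
| `hr_ckd_mort_treated` | 0.83 (0.78–0.87) | death HR, treated vs untreated CKD |
| `rr_esrd_treated` | 0.79 (0.70–0.90) | ESRD-onset RR under ACEI/ARB treatment |
| `p_esrd_base` | 0.10 | annual pre-end-stage → ESRD probability |
| `p_ckd_incidence` | 0.0 | annual AT_RISK → CKD onset (closed cohort) |

Numerical conventions:

- rates convert to probabilities by `p = 1 − exp(−r)` (implemented with
  `expm1` for small-rate accuracy);
- hazard ratios act on the hazard scale, `p′ = 1 − (1 − p)^HR`, which
  composes exactly (HR a then b equals HR a·b);
- relative risks act multiplicatively with clipping at 1;
- the ESRD mortality figure 3.38% is an annual proportion from a registry
  report and is used directly, not rate-converted;
- death competes first within a cycle: the entry to ESRD is
  `(1 − p_death) · p_onset`, which keeps rows on the simplex for every
  parameter value in the published ranges.

Two readings were possible for the treated-mortality figure 0.83: treated
vs untreated CKD, or treated CKD vs the general population. We adopt the
first and compose it with 1.63 (net hazard scaling 1.353 vs the general
population); under the second reading treatment would make CKD mortality
*lower* than the general population's, which is clinically implausible
for a kidney-protective therapy. Similarly, the baseline annual
pre-end-stage → ESRD probability is not printed unambiguously; we default
to 0.10, the midpoint of the published annotation "(8.89, 11.13%)", and
expose it as ordinary configuration.

## Screening strategies

A strategy is an any-of eligibility predicate over
{hypertension, diabetes, age ≥ 65} (age evaluated at the screening event,
after aging), a schedule, per-test costs (4 yuan urinalysis + 8 yuan
creatinine) and a participation proportion (default 1.0 — full
participation, exposed as a dial because real programmes fall short of
it). The five built-ins cover the hypertension group, the diabetes group,
their union, the 65-and-older group, and the union of all three.

The default schedule screens at baseline only: the simulated question is
the ten-year evolution of burden for patients identified in the starting
year. Annual re-screening is available via `schedule: annual`. The
screening test is perfect (sensitivity = specificity = 1): every screened
pre-end-stage CKD case is detected and started on treatment the same
year. Screening never changes the state of AT_RISK or ESRD individuals —
they only accrue the test cost.

## Simulation engine

Cycle order each year: **screen → transition → age → account**. Year-one
screening therefore affects year-one transitions, so paired arms diverge
immediately. There is no half-cycle correction; an individual who dies
within a year accrues zero QALYs and zero outpatient cost for that year
(end-of-cycle accrual).

Randomness: a master seed yields one uniform per (individual, year) from
a per-year child stream (`default_rng([master_seed, year])`, indexed by
cohort position). Paired arms consume identical uniforms (common random
numbers), and extending the horizon never re-draws earlier years.
Transitions are sampled by inverse transform against a fixed destination
ordering with the worst outcomes first (DEAD, then ESRD, then the
remaining states). Because the treated row's death and ESRD probabilities
are dominated by the untreated row's, this ordering guarantees per-draw
dominance: an individual who dies (or reaches ESRD) under the
intervention does so under control too. The suite asserts the resulting
cumulative dominance on full trajectories.

The engine also ships a deterministic oracle, `expected_occupancy`: the
initial state-count vector propagated through matrix powers. The
micro-simulation's mean occupancy over replicates must match it within
Monte-Carlo error for every state and year; this is tested at 500
replicates of a 200-person cohort over 5 years.

## Burden accounting

QALY weights: 1.0 at risk, 0.81 pre-end-stage (all three compartments),
0.658 ESRD, 0 dead. Costs: outpatient 4,159 yuan/yr (stages I–IV) and
107,209 yuan/yr (stage V); ACEI/ARB treatment 52 × 30 yuan/yr charged to
`CKD_TREATED` person-years only (the therapy targets pre-end-stage
disease); screening 12 yuan per screened person. ESRD years accrue the
stage V outpatient figure only, not additionally the stage I–IV figure.

Costs are discounted at 5%/yr relative to the start year (year 1 is
undiscounted). QALYs are **not** discounted by default — the 5% rate is
stated for costs — but `discount_qalys: true` enables standard practice.
Per-capita QALYs divide by the *initial* cohort size, a constant, so the
trajectory declines as deaths accumulate; a survivor denominator would
not show the burden of mortality at all. All internal arithmetic is in
yuan at full precision; million-yuan values are rounded (half-up) only at
the report layer.

## Sensitivity analysis

One-way, deterministic, ±10%, three factor groups:

- **transition probabilities** — the derived annual matrix's off-diagonal
  event probabilities are scaled (not the underlying rates or HRs), with
  clipping and diagonal renormalization;
- **costs** — all unit costs including the strategy's screening test
  prices (the discount rate is not a cost and is untouched);
- **utilities** — living-state utilities, clipped at 1 because perfect
  health is a ceiling; downward perturbations never clip.

Perturbed runs reuse the base case's master seed, so trajectories are
identical whenever transitions are unperturbed and the deltas are exact:
cost ±10% moves the discounted burden by exactly ±10%, and utility ±10%
moves QALYs by exactly ±10% on cohorts with no full-health members (the
ceiling makes +10% sub-linear when AT_RISK members are present — the
asymmetry published tornado tables show). Outputs per arm: mean annual
discounted burden over the horizon, and final-year per-capita QALYs.

## Synthetic cohort

The generator emulates a screened high-risk cohort's microdata: 35,412
individuals; ages from Normal(71.45, 8.18) truncated below at 45, sampled
by inverse CDF, floored to whole years (the source tabulates 5-year bins
labelled by lower edge; half-open [x, x+5) bins reproduce the published
bin masses, e.g. [70, 75) analytic mass 23.8% vs printed 23.9%), with the
sliver above 105 folded into the terminal [100, 105) bin.

Entry states: `ckd_prevalence` (default 0.2575, the published screening
detection rate — the only printed prevalence for this population) enter
with CKD; of those, `stage_v_fraction` (default 0.02, from the 214 / 10,722
patient counts behind the cost table) enter as ESRD, and
`detected_fraction` (default 0.25, our choice: roughly the share of
screened CKD known before screening in the source database) of the
remainder enter already diagnosed. Hypertension and diabetes prevalences
within the cohort are not published; they default to 0.5 each,
independent, and any under-65 member drawn with neither flag receives one
(in proportion to the prevalences) so that every member is genuinely
high-risk. These four values are honest configuration, not calibrated
fits.

What the generator does **not** emulate: the source cohort's deviation
from normality in the outer age bins (likely post-stratification to the
real stage distribution), sex structure, risk-factor correlation with
age, and co-occurrence of hypertension and diabetes beyond independence.
Passing tests therefore show the machinery is correct under the stated
distributional conditions, not that the defaults reproduce any particular
city's absolute case counts — the per-scenario cohort compositions behind
the published absolute tables are not recoverable, so those absolute
numbers are out of reach at any seed (the published summary *arithmetic*
is verified directly on the printed values instead).

## Problem sizes used in the test suite

Unit and property tests run cohorts of 200–5,000 for 1–10 years; the
oracle-equivalence check uses 500 replicates × 200 individuals × 5 years;
dominance and sensitivity checks use 1,000–3,000-person cohorts over 6–10
years. These sizes put Monte-Carlo standard errors well below the asserted
tolerances while keeping the default suite around a few seconds. The
full-scale 35,412 × 10-year paired run takes ~2 s and is exercised via the
CLI.

## Known limitations

- Single crude mortality rate: no age- or sex-specific schedules (the
  published model uses one rate), so the very old are under-penalized.
- No CKD regression, no transplant pathway, no dialysis-modality split.
- Perfect screening test and full default participation overstate
  real-world programme effects; both are exposed as dials.
- Direct medical costs only (outpatient, tests, ACEI/ARB); no inpatient,
  transport or productivity costs.
- One-way sensitivity only; no probabilistic sensitivity analysis.
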