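# Methods

## The model

`mhsd` implements a deterministic system-dynamics (stock-and-flow) model of
a regional mental-health system with four interacting components:

1. **Population** — a single aggregate population per district, growing
   through a constant births + net-migration inflow and depleted by
   proportional background mortality and suicide deaths.  No age or sex
   stratification.
2. **Psychological distress** — people are *well* (K10 ≤ 15) or
   *distressed* (K10 ≥ 16; the unassigned K10 = 15 band is grouped with
   "well", the conventional banding).  Distress onset moves well people
   into the distressed pool at `distress_onset_rate`/yr, multiplied during
   the pandemic pulse (below); untreated recovery returns them.
3. **Services** — distressed people seek help at `help_seeking_rate`/yr
   and travel a primary-to-tertiary pathway: a GP queue and GP care,
   referral onward to a specialist (psychiatrist/allied) queue and care,
   community mental healthcare (CMHC), psychiatric inpatient care (which
   steps down into CMHC), or online services.  Each in-person service has a
   weekly capacity (events/week) that compounds at an annual growth rate;
   dividing by a per-person service intensity (contacts per person-year)
   converts capacity into a maximum caseload.  Queue waits follow Little's
   law (queue / weekly intake, capped at 52 weeks).  Disengagement from
   queues and care happens at `base_disengagement_rate` plus a linear
   wait-time term (`disengagement_wait_sensitivity` per week of wait),
   capturing the loss of patients as congestion grows; disengaged people
   may re-engage via the GP queue or recover untreated.
4. **Suicidal behaviour** — suicide attempts arise at state-specific
   hazards (untreated > in-care, by assumption enforced at construction;
   post-attempt much higher).  A fixed `hospitalised_fraction` of attempts
   is counted as a self-harm hospitalisation (the standard administrative
   proxy for attempts) and a fixed `attempt_case_fatality` dies; survivors
   move to a post-attempt state that either engages with CMHC-delivered
   aftercare or returns to the distressed pool.  ED presentations are
   generated as *events* (not person flows) from crisis states and from
   every attempt.

The three minimised outcomes are cumulative suicide deaths, mental-health
ED presentations and disengagement events over the 2021–2031 forecast
window.

### Structure choice

The 11-stock structure above is one concrete realisation of the
four-component causal structure; the complete stock-flow diagram and
parameter table of the original regional model are not publicly available.
Every rate is exposed in `ModelParams`, and the structure is contained in a
single module so alternative structures can be slotted in.

### Integration

Explicit Euler at dt = 0.4375 days (one sixteenth of a week), the standard
step of system-dynamics tooling for these smooth dynamics, over 28 years
from 1 January 2011.  Time is fractional years on a 365-day calendar, so
the horizon is exactly 23,360 steps; calendar effects are ignored.  All
outflows from a stock are jointly rationed (scaled proportionally) whenever
an Euler step would overdraw it, which prevents negative stocks without
privileging any flow.  Halving the step changes 28-year cumulative outcomes
by far less than 1% (asserted in the test suite), so the calibration
objective runs on a 4× coarser grid (1.75 days) to keep derivative-free
search affordable; everything else uses the canonical step.

Person conservation — at every step the population changes exactly by
(births + migration − background deaths − suicide deaths)·dt — holds to
floating-point precision and is asserted across the full default run.

### The pandemic pulse

Distress-onset incidence is multiplied by `onset_multiplier` (default
1.075) over a rectangular pulse starting 1 March 2020 with default duration
2 years.  Only onset is shocked.  The default multiplier was fixed once so
the baseline suicides/yr series rises ≈6% from early 2020 to late 2021,
the observed shape of the regional projection this package emulates.

## Interventions

`catalogue.yaml` declares the 12 entries: 8 programs (post-attempt
assertive aftercare, GP training, community education, family
psychoeducation, safety planning, safe-space ED alternative, social
connectedness, community-based acute care) and 4 capacity levers (GP,
specialist, inpatient growth multipliers; an additive CMHC increment in
contacts per 10,000 population per week, default 0).  Each program lists
`(parameter_path, transform, effect)` targets; magnitudes are documented
package defaults anchored to the intervention literature (e.g. aftercare
re-attempt hazard ratio 0.70), scaled so four-intervention combinations
produce reductions in the 5–20% band.  They are editable data, not code.

Scenarios roll out instantaneously at 1 Jan 2021 at full scale.  Effects on
shared parameters combine multiplicatively (order-independent,
positivity-preserving); fractions pushed outside [0,1] are clamped with a
warning.  Non-additive interaction between interventions emerges
structurally — most importantly through shared CMHC capacity: aftercare
consumes `aftercare_cmhc_cost` CMHC contacts/week for every person in the
post-attempt state, shrinking the free CMHC caseload, raising the CMHC
congestion signal and hence disengagement.  This is the mechanism behind
the suicide-versus-disengagement trade-off the scenario search exposes.
Community education's effect is scaled by a community-support factor,
linear in social-connectedness coverage (1.0 alone, 1.5 when the
connectedness program is active).  Safe-space and acute-care diversion
fractions act on the ED flow *before* counting, so diverted contacts never
increment the ED outcome; acute-care diversions additionally enter
CMHC-style care, capacity permitting.

## Calibration

Free parameters are fitted to six annual observation series (distress
prevalence, self-harm hospitalisation rate, suicide rate, GP mental-health
consultations/yr, allied services/yr, psychiatric bed occupancy) by
minimising the **sum of per-series MAPE** — each absolute observed−simulated
difference expressed as a percent of the observed value, averaged within a
series, summed across series.  Model output is linearly interpolated to the
observation timestamps.  The observed series must be strictly positive
(MAPE denominators).

The search is Powell's conjugate-direction method in unit-box-normalised
coordinates with native box constraints plus a quadratic penalty for any
excursion; simulation failures inside the objective return a large finite
penalty rather than raising.  Defaults: xtol 1e-4 (normalised), ftol 1e-6,
up to 3 jittered restarts (seeded), best kept.  Which parameters are free
is a configuration list, defaulting to six of the least-evidenced rates.

**Identifiability.**  On the generate-and-refit fixture the six observed
series pin down the attempt hazard, specialist referral rate, case
fatality and base disengagement rate individually (refit errors ≪1%
noiseless), but distress onset and untreated recovery form a sloppy pair:
the prevalence level constrains their *ratio* while their common scale is
only weakly informed, so refits wander 10–20% along that direction at
near-zero objective.  `SyntheticTruth.identifiable` records the subset for
which point recovery is meaningful; recovery assertions (within 5%
noiseless, 15% at 5% observation noise) apply to it.

## Scenario search and Pareto filtering

All C(12, 4) = 495 unordered combinations are evaluated per district.  The
pre-2021 segment is simulated once per district and shared across scenarios
(exact, since interventions act only from the start date).  Outcomes are
cumulative counter differences over the window; the regional (PHN) outcome
is the component-wise sum of the two districts.  Percent reductions are
100·(baseline − scenario)/baseline against a baseline evaluated once.

Domination is the standard weak-Pareto rule for minimisation: `a` dominates
`b` iff `a ≤ b` on all three outcomes and `a < b` on at least one;
identical triplets are all retained on the front.  The vectorised filter is
property-tested against an O(n²) all-pairs oracle on 1000 random tables.
Best-per-outcome is the argmin with lexicographic tie-breaking.  Scenario
letter labels (a, b, …) are assigned by descending suicide reduction.

## Sensitivity analysis

Latin hypercube sampling (scipy's implementation; exactly one draw per
equal-probability stratum per margin, uniform within strata — the
maximum-entropy choice on a bounded range) draws 100 parameter sets by
default: one dimension per program's direct effect, as a scale factor on
its distance from identity in [0.8, 1.2] (±20%), plus the pandemic-pulse
duration in ±50% of its default.  Capacity levers are policy settings, not
uncertain effects, and carry no dimension; the connectedness coverage
switch is likewise excluded (`vary: false`).  Each draw rebuilds the
catalogue and parameters and re-runs the scenario pipeline; failed draws
are recorded as NaN, not fatal.  Summaries are means with 50% and 95%
empirical intervals (linear interpolation between order statistics).  The
intervals measure the impact of assumed-effect uncertainty on projections;
they are not confidence intervals.

## Synthetic data

No public microdata exist for the modelled region, so `synthetic` builds
two district configurations from published summary statistics: total
population 1,269,782 (2018), split 73.5%/26.5% by burden share; distress
13.5 per 100 adults; suicide mortality 13.7 per 100,000/yr (≈174
deaths/yr); service supply per million population chosen so baseline
utilisation sits near capacity (the near-maximum-capacity operating
assumption).  The default `ModelParams` were tuned once against these
statistics — prevalence, suicide/ED/disengagement rates, the ≈6% pandemic
rise, and 2021–2031 cumulative totals within ~5% of the emulated regional
projections — and then frozen.

Generated "historical" series are annual end-of-year samples of the six
calibration outputs over 2011–2017, multiplied by mean-one lognormal noise
with a given coefficient of variation (multiplicative noise keeps the
series strictly positive; annual cadence matches the public data sources
such series come from).  For small cv the expected MAPE between clean and
noisy series is 100·cv·√(2/π) (half-normal mean), which the tests verify
by Monte Carlo.

What the generator does **not** emulate: age/sex structure, seasonality,
reporting artefacts, within-year cadence differences between sources, and
cross-district correlation of observation errors.  Passing tests therefore
demonstrate that the machinery is correct under the stated statistical
structure, not that the defaults reproduce the confidential region.

## Numerical choices and problem sizes

- Wait-time cap 52 weeks; saturated services (zero throughput, non-empty
  queue) report the cap.
- CMHC congestion is expressed as fractional caseload overload mapped to a
  weeks-of-backlog scale (10% overload ≈ 5.2 weeks).
- Intake flows are limited by remaining caseload room × intake rate, which
  keeps caseloads at or below capacity for any dt with intake_rate·dt ≤ 1.
- Powell tolerances above; calibration grid 1.75 days; recovery-fixture
  targets are generated on that same grid so the noiseless objective is
  exactly zero at the truth.
- The default test/acceptance problem sizes are the full 495-combination
  search at the canonical step, a 20-draw sensitivity sweep over the three
  leading scenarios, and single-restart Powell fits (30 iterations max) on
  the six-parameter fixture; these sizes were chosen to run comfortably on
  one CPU while exercising every stage at full structural fidelity.

## Known limitations

- Self-harm hospitalisations are an events counter, not a patient flow
  into inpatient care; the under-enumeration inherent in the proxy is
  shared by baseline and scenarios, so percent reductions are unaffected.
- Districts are independent (no cross-district patient flow); the regional
  total is their sum.
- No costing, budget constraints, staged rollouts, or agent-level
  heterogeneity.
- The rectangular pandemic pulse shocks distress onset only; service
  capacity is assumed unaffected.
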