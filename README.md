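# mhsd — regional mental-health system dynamics

`mhsd` is a stock-and-flow simulation and decision-analysis toolkit for
regional mental-health systems.  It is built for the planning question a
regional commissioning body faces: out of a catalogue of suicide-prevention
programs and service-capacity investments, **which combination best reduces
suicide deaths, mental-health emergency-department (ED) presentations and
service disengagement — and how do those three goals trade off against each
other** across the districts that make up a region?

The package models a two-district region (a large inland district carrying
~74% of the burden and a smaller coastal one, together ~1.27 million
people) with:

- an 11-stock system-dynamics core: psychological distress (K10-banded),
  help seeking, GP / specialist / community (CMHC) / inpatient / online
  service pathways with capacity-limited caseloads, queue waits (Little's
  law), wait-sensitive disengagement, and suicidal behaviour with
  state-specific attempt hazards, a hospitalised fraction and a case
  fatality — integrated by explicit Euler at one sixteenth of a week over
  28 years from 2011;
- a catalogue of 12 interventions (8 programs + 4 capacity levers) mapped
  onto model parameters, with capacity-consuming programs (post-attempt
  aftercare runs through existing CMHC services) so combinations interact
  structurally;
- calibration of free parameters by Powell's derivative-free method
  minimising the sum of per-series mean absolute percent errors (MAPE)
  against six annual historical series;
- exhaustive evaluation of all C(12,4) = 495 four-intervention scenarios
  over 2021–2031, percent reductions versus business as usual, and
  extraction of the non-dominated (Pareto-optimal) set across the three
  outcomes;
- Latin-hypercube sensitivity analysis (±20% on program effects, ±50% on
  the pandemic-pulse duration) with 50%/95% interval summaries;
- a synthetic-data generator that reproduces the region's published summary
  statistics (population 1,269,782; distress 13.5 per 100; suicides 13.7
  per 100,000/yr) so the full pipeline runs with no confidential data.

## Worked example

```python
from mhsd import (
    default_configs, default_params, simulate, cumulative_outcomes,
    aggregate_regions, pareto_front,
)
from mhsd.engine import date_to_t
from mhsd.scenarios import evaluate_scenarios, best_per_outcome

configs = default_configs()          # the two synthetic districts
params = default_params()
window = (date_to_t("2021-01-01"), date_to_t("2031-01-01"))

# business-as-usual projection, 2021-2031
outs = [cumulative_outcomes(simulate(c, params, t_end=20.5), window)
        for c in configs]
phn = aggregate_regions(outs)
print(round(phn.suicides), round(phn.ed_presentations),
      round(phn.disengagements))
# 1736 161334 535162

# exhaustive 4-of-12 scenario search with Pareto filtering (~3 min)
table = evaluate_scenarios(configs, params, k=4, window=window)
front = pareto_front(table, "PHN")
print(len(front.non_dominated))
# 9
print(best_per_outcome(table, "PHN", "suicides"))
# cap_gp+family_psychoeducation+safety_planning+social_connectedness
```

Under business as usual the synthetic region accumulates ≈1736 suicides,
≈161,000 mental-health ED presentations and ≈535,000 disengagement events
over the decade.  Nine four-intervention combinations are Pareto-optimal:
none of them is beaten on all three outcomes by any other combination, so
they are equally defensible choices depending on which outcome a
decision-maker prioritises.  The suicide-minimising combination cuts
suicides by ~14% but is *not* the combination that minimises
disengagement — intensive suicide-prevention programs consume community
mental-healthcare capacity, lengthen effective waits and push more patients
out of care, which is the central trade-off the package is designed to
expose.

A command-line interface wraps the same pipeline:

```sh
mhsd pipeline --seed 1 --k 4 --n-sensitivity 20 --out results/
mhsd simulate --region 0 --out trajectory.csv
mhsd make-synthetic --seed 1 --out synth/
mhsd calibrate --targets synth/targets_HNE.csv --out fitted.json
```

## Layout

| module | contents |
| --- | --- |
| `mhsd.engine` | stocks, parameters, Euler stepper, trajectories, outcomes |
| `mhsd.interventions` | the 12-entry catalogue (`catalogue.yaml`) and its mapping onto parameters |
| `mhsd.calibration` | MAPE objective and Powell box-constrained fitting |
| `mhsd.scenarios` | k-of-12 enumeration, evaluation, domination and Pareto front |
| `mhsd.sensitivity` | Latin-hypercube designs, sweep, interval summaries |
| `mhsd.synthetic` | district profiles, history generation, recovery fixture |
| `mhsd.reporting` | outcome tables, annualised series, pipeline driver |
| `mhsd.cli` | `mhsd` command group |

See `docs/methods.md` for the model's assumptions, parameter meanings,
numerical choices and known limitations.
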