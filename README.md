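# oebench

Benchmarking **observed-vs-expected (O/E) background-rate comparison designs**
for vaccine-safety signal detection, on fully synthetic observational health
data.

The package simulates an OMOP-style event dataset (persons, observation
periods, outpatient visits, vaccination exposures, outcome occurrences) with
configurable bias mechanisms, then evaluates how well historical-rate
comparison detects safety signals:

1. **synthetic data** — age/sex-structured population, rapid (flu-like) or
   slow (HPV-like) vaccine uptake, per-outcome Poisson event processes with
   age/sex/seasonal/secular structure, and three switchable bias knobs:
   age confounding of vaccination, a healthy-vaccinee rate shift, and
   boosted outcome recording near healthcare visits.
2. **incidence** — background (historical) and post-vaccination incidence
   rates under four designs: unadjusted, age-sex adjusted, visit-anchored,
   and anchored + adjusted; monthly data accrual for timeliness.
3. **control synthesis** — negative-control outcomes pass through; positive
   controls are synthesized by injecting extra events in the day 1–28
   post-vaccination window at true IRRs 1.5, 2 and 4 (skipped for parents
   with fewer than 25 exposed-window events).
4. **estimation** — IRR = O/E with Wald CI, exact one-sided Poisson tail
   p-value, and the one-sided Poisson MaxSPRT log likelihood ratio.
5. **calibration** — empirical calibration: a Gaussian systematic-error
   model (mean, SD on the log-IRR scale) fitted by maximum likelihood to
   control estimates, applied leave-one-out.
6. **evaluation** — type 1 / type 2 error, AUC, CI coverage, geometric mean
   precision, MSE, estimability filtering (including the >50% monthly
   rate-change exclusion) and first-detection timeliness.
7. **pipeline** — end-to-end orchestration with file-based stage handoffs
   and a reproducibility manifest.

## CLI

```bash
# everything at once (bundled demo config)
oebench run --config src/oebench/configs/quickstart.yaml --out runs/demo --plots

# or stage by stage
oebench simulate  --config src/oebench/configs/flu_like.yaml --out runs/flu
oebench synthesize --out runs/flu
oebench estimate   --out runs/flu
oebench calibrate  --out runs/flu
oebench evaluate   --out runs/flu
oebench report     --out runs/flu --plots
```

Outputs per run directory: the five simulated tables (`tables/`), the
augmented outcome table, a control manifest, an estimates table (one row per
control × design × accrual month, calibrated fields included), a metrics
table (one row per design × calibration flag × month), an exclusion log,
first-detection months, a markdown summary and a `manifest.json` with file
digests for reproducibility checks.

Configs are YAML (see `src/oebench/configs/` for the schema by example);
`--seed` overrides the scenario seed everywhere.

## Python API

```python
from oebench import (
    ScenarioConfig, simulate_scenario, synthesize_positive_controls,
    TimeAtRiskWindow, historical_rates, observed_rates, estimate_effect,
    fit_systematic_error, leave_one_out_calibrate, run_experiment,
)
from oebench.fixtures import scenario_profile

cfg = scenario_profile("visit_capture", n_persons=10_000, seed=1)
tables = simulate_scenario(cfg)
```

Conventions: days are integers (day 0 = scenario origin), intervals are
half-open `[start, end)`, months are 30-day blocks, rates are events per
person-year, and all incidence is first-event-per-person within the window
at hand.

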