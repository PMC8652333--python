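# Minimal end-to-end demo: 2,000 persons, 12 negative controls, 1 vaccine.
# Rates are set high so positive-control synthesis has material to work with
# at this tiny scale.
scenario_id: quickstart
scenario:
  n_persons: 2000
  seed: 7
  female_fraction: 0.511
  visit_rate: 3.0
  vaccine_id: flu_like
  surveillance_months: 12
  uptake: {kind: rapid, coverage: 0.4}
  outcomes:
    negative_controls: {n: 12, base_rate: 1.0, rate_spread: 2.0}
analysis:
  tar: [1, 28]
  irrs: [1.5, 2, 4]
  min_outcomes: 25
  accrual_months: [6, 12]
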