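# Slow-uptake campaign (HPV / varicella-zoster style): 12 surveillance
# months, doses spread roughly uniformly.
scenario_id: hpv_like
scenario:
  n_persons: 20000
  seed: 13
  female_fraction: 0.5623
  visit_rate: 3.0
  vaccine_id: hpv_like
  surveillance_months: 12
  uptake: {kind: slow, coverage: 0.4}
  outcomes:
    negative_controls: {n: 40, base_rate: 0.3, rate_spread: 2.0}
analysis:
  accrual_months: [2, 4, 6, 9, 12]
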