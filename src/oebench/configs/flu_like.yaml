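# Rapid-uptake campaign (H1N1 / seasonal-flu style): 9 surveillance months,
# most doses in the first two months.
scenario_id: flu_like
scenario:
  n_persons: 20000
  seed: 11
  female_fraction: 0.511
  visit_rate: 3.0
  vaccine_id: flu_like
  surveillance_months: 9
  uptake: {kind: rapid, coverage: 0.4}
  outcomes:
    negative_controls: {n: 40, base_rate: 0.3, rate_spread: 2.0}
analysis:
  accrual_months: [1, 2, 3, 6, 9]
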