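# Small synthetic demo: ~60 s end to end on one CPU.
seed: 1
out_dir: scratch/demo_out
responses: [hb, plt]
stratifiers: [sex, age_group]
simulate:
  n_stations: 5
  use_network: true
  climate:
    start_date: 2013-01-01
    end_date: 2017-12-31
  cohort:
    n_subjects: 250
    visit_rate: 2.0
  truth:
    exposure_effects:
      - {response: hb, definition_id: HW05, lag: lag1, effect: 2.6}
      - {response: plt, definition_id: CS07, lag: lag2, effect: -3.85}
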