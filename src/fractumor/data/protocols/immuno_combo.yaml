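name: immuno_combo
schedules:
- drug_type: chemo
  kind: cyclic
  dose: 0.6
  treatment_days: 7
  rest_days: 14
  start_day: 0.0
  monitoring_period: 21.0
  target_ratio: 1.0
  min_dose: 0.6
  max_dose: 0.9
  step: 0.1
- drug_type: immuno
  kind: cyclic
  dose: 0.7
  treatment_days: 2
  rest_days: 19
  start_day: 0.0
  monitoring_period: 21.0
  target_ratio: 1.0
  min_dose: 0.6
  max_dose: 0.9
  step: 0.1
hyperthermia: null
resistance_parameter: null
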