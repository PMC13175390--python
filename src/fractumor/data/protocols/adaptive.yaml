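name: adaptive
schedules:
- drug_type: hormone
  kind: adaptive
  dose: 0.75
  treatment_days: 14.0
  rest_days: 7.0
  start_day: 0.0
  monitoring_period: 21
  target_ratio: 1.0
  min_dose: 0.6
  max_dose: 0.9
  step: 0.1
- drug_type: her2
  kind: adaptive
  dose: 0.75
  treatment_days: 14.0
  rest_days: 7.0
  start_day: 0.0
  monitoring_period: 21
  target_ratio: 1.0
  min_dose: 0.6
  max_dose: 0.9
  step: 0.1
hyperthermia: null
resistance_parameter: adaptive_resist_dev
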