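parameters:
  lambda1: 0.003
  lambda2: 0.002
  beta1: 0.005
  omega_r1: 0.004
  omega_r2: 0.003
  mutation_rate: 0.0001
  metabolic_switch_rate: 0.02
  hypoxia_threshold: 0.3
  circadian_amplitude: 0.2
  circadian_period: 1.0
  circadian_phase: 0.0
  absorption_rate: 0.5
  elimination_rate: 0.1
  bioavailability: 0.85
  ec50: 0.3
  hill_coef: 1.5
  max_drug_effect: 1.0
  distribution_vol: 70.0
  eta_e: 0.01
  eta_h: 0.01
  eta_c: 0.01
  treatment_cycle_period: 21.0
  treatment_active_days: 7.0
  rest_period_days: 14.0
  treatment_intensity: 1.0
  age_factor: 1.0
  performance_status: 1.0
  bmi_factor: 1.0
  immune_status: 1.0
  liver_function: 1.0
  kidney_function: 1.0
  prior_treatment_factor: 1.0
  carrying_capacity: 1000.0
  phi1: 0.1
  phi2: 0.001
  phi3: 0.0003
  beta2: 0.001
  delta_i: 0.04
  lambda_r1: 0.006
  lambda_r2: 0.005
  gamma_met: 0.0001
  delta_p: 0.01
  alpha_a: 0.01
  delta_a: 0.1
  kappa_q: 0.001
  lambda_q: 0.0005
  kappa_s: 0.0005
  delta_s: 0.005
  epigenetic_silencing: 0.002
  genetic_instability: 1.0
  acidosis_factor: 0.01
  immune_resist_factor1: 0.1
  immune_resist_factor2: 0.05
  continuous_resist_dev: 2.0
  adaptive_resist_dev: 1.2
  immuno_resist_boost: 0.5
  resistance_floor: 0.01
  microenv_stress_factor: 1.0
category:
  lambda1: experimental
  lambda2: experimental
  beta1: experimental
  omega_r1: experimental
  omega_r2: experimental
  mutation_rate: experimental
  metabolic_switch_rate: experimental
  hypoxia_threshold: experimental
  circadian_amplitude: experimental
  circadian_period: experimental
  circadian_phase: experimental
  absorption_rate: clinical
  elimination_rate: clinical
  bioavailability: clinical
  ec50: clinical
  hill_coef: clinical
  max_drug_effect: clinical
  distribution_vol: clinical
  eta_e: clinical
  eta_h: clinical
  eta_c: clinical
  treatment_cycle_period: clinical
  treatment_active_days: clinical
  rest_period_days: clinical
  treatment_intensity: clinical
  age_factor: clinical
  performance_status: clinical
  bmi_factor: clinical
  immune_status: clinical
  liver_function: clinical
  kidney_function: clinical
  prior_treatment_factor: clinical
  carrying_capacity: literature
  phi1: literature
  phi2: literature
  phi3: literature
  beta2: literature
  delta_i: literature
  lambda_r1: literature
  lambda_r2: literature
  gamma_met: literature
  delta_p: literature
  alpha_a: literature
  delta_a: literature
  kappa_q: literature
  lambda_q: literature
  kappa_s: literature
  delta_s: literature
  epigenetic_silencing: literature
  genetic_instability: literature
  acidosis_factor: literature
  immune_resist_factor1: hypothetical
  immune_resist_factor2: hypothetical
  continuous_resist_dev: hypothetical
  adaptive_resist_dev: hypothetical
  immuno_resist_boost: hypothetical
  resistance_floor: hypothetical
  microenv_stress_factor: hypothetical
circadian_enabled: true
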