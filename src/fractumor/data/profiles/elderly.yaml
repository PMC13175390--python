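name: elderly
age_factor: 0.8
performance_status: 0.8
immune_status: 0.7
liver_function: 0.9
kidney_function: 0.85
mutation_rate: 0.00015
genetic_instability: 1.0
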