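name: average
age_factor: 1.0
performance_status: 1.0
immune_status: 1.0
liver_function: 1.0
kidney_function: 1.0
mutation_rate: 0.0001
genetic_instability: 1.0
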