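name: young
age_factor: 1.2
performance_status: 1.2
immune_status: 1.3
liver_function: 1.1
kidney_function: 1.1
mutation_rate: 8.0e-05
genetic_instability: 1.0
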