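name: compromised
age_factor: 0.8
performance_status: 0.7
immune_status: 0.6
liver_function: 0.7
kidney_function: 0.7
mutation_rate: 0.00015
genetic_instability: 1.2
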