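{
 "Dummy features only": 0.05,
 "Sex only": 0.06,
 "Basic name features": 0.51,
 "Name substring features": 0.56,
 "Numeric name features": 0.16,
 "Phonetic name features": 0.31,
 "All name features": 0.6,
 "All location features": 0.41,
 "All name and location features": 0.72
}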