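patient_id,r_squared
1,0.197
2,0.362
3,0.046
4,0.023
5,0.050
6,0.495
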