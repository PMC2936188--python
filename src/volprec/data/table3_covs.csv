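patient_id,left_adrenal_cov_pct,right_adrenal_cov_pct
1,15.0,23.5
2,17.8,18.8
3,21.0,11.7
4,20.4,21.8
5,14.4,19.1
6,18.2,20.0
7,,17.5
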