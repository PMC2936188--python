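patient_id,left_adrenal_cm3,right_adrenal_cm3
1,5.6,2.8
2,3.8,2.7
3,6.9,8.4
4,4.6,3.5
5,6.5,3.4
6,8.0,5.1
7,,5.7
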