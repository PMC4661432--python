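record,k21_per_h,k12_per_h,A_WB,B_WB,MR,kel_per_h
population_estimate,0.0163,0.0096,0.105,0.14,,
population_sd,0.0014,0.0009,0.004,0.01,,
patient_1_indium,0.0152,0.0101,0.097,0.13,124.2,0.18
patient_1_lutetium,0.0177,0.0094,0.110,0.15,125.5,0.23
patient_2_indium,0.0126,0.0100,0.104,0.14,40.7,0.18
patient_2_lutetium,0.0138,0.0101,0.115,0.16,40.1,0.21
patient_3_indium,0.0178,0.0090,0.115,0.16,35.7,0.20
patient_3_lutetium,0.0197,0.0085,0.121,0.17,37.8,0.23
patient_4_indium,0.0136,0.0099,0.097,0.14,22.6,0.15
patient_4_lutetium,0.0166,0.0099,0.089,0.13,22.0,0.13
patient_5_indium,0.0146,0.0104,0.098,0.14,22.5,0.15
patient_5_lutetium,0.0165,0.0102,0.083,0.12,31.1,0.13
patient_6_indium,0.0141,0.0101,0.071,0.11,109.0,0.12
patient_6_lutetium,0.0166,0.0098,0.091,0.13,18.8,0.13
patient_7_indium,0.0143,0.0101,0.102,0.14,3.3,0.12
patient_7_lutetium,0.0191,0.0090,0.070,0.13,3.2,0.08
patient_8_indium,0.0141,0.0100,0.110,0.15,2.3,0.12
patient_8_lutetium,0.0190,0.0090,0.098,0.14,2.5,0.11
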