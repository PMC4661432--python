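record,k21_per_h,k12_per_h,kel_per_h,vol_per_m2_L,vc_L,clearance_L_per_h
population_estimate,0.034,0.0075,0.182,1.86,,
population_sd,0.002,0.0005,0.003,0.04,,
patient_1,0.033,0.0062,0.194,2.00,4.01,0.78
patient_2,0.033,0.0080,0.177,1.82,2.71,0.48
patient_3,0.036,0.0081,0.169,1.83,4.93,0.84
patient_4,0.036,0.0071,0.182,1.80,3.33,0.61
patient_5,0.034,0.0075,0.183,1.81,3.05,0.56
patient_6,0.033,0.0085,0.174,1.84,3.20,0.56
patient_7,0.035,0.0068,0.183,1.92,3.73,0.68
patient_8,0.035,0.0073,0.177,1.77,3.45,0.61
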