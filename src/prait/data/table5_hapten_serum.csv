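record,k21_per_h,k12_per_h,A_S,B_S,MR,kel_per_h,vol_per_m2_L,vc_L,clearance_L_per_h
population_estimate,0.027,0.019,1.42,0.182,,,6.38,,
population_sd,0.001,0.002,0.07,0.012,,,0.27,,
patient_1_indium,0.027,0.021,1.35,0.169,124.2,0.226,6.69,13.4,3.04
patient_1_lutetium,0.024,0.021,1.37,0.172,125.5,0.241,6.50,13.1,3.15
patient_2_indium,0.026,0.023,1.31,0.167,40.7,0.250,6.54,9.7,2.43
patient_2_lutetium,0.027,0.022,1.22,0.156,40.1,0.219,6.63,9.9,2.16
patient_3_indium,0.028,0.015,1.53,0.199,35.7,0.185,6.23,16.8,3.11
patient_3_lutetium,0.028,0.017,1.43,0.183,37.8,0.165,6.25,16.8,2.78
patient_4_indium,0.026,0.026,0.92,0.141,22.6,0.112,6.90,12.7,1.43
patient_4_lutetium,0.029,0.019,1.29,0.167,22.0,0.173,6.78,12.5,2.17
patient_5_indium,0.027,0.017,1.53,0.196,22.5,0.235,6.15,12.0,2.82
patient_5_lutetium,0.028,0.017,1.52,0.196,31.1,0.249,6.13,11.9,2.97
patient_6_indium,0.027,0.019,1.41,0.179,109.0,0.291,6.44,11.2,3.25
patient_6_lutetium,0.028,0.021,1.31,0.170,18.8,0.179,6.93,12.0,2.15
patient_7_indium,0.027,0.022,1.41,0.181,3.3,0.146,6.21,12.0,1.76
patient_7_lutetium,0.028,0.018,1.41,0.181,3.2,0.137,6.54,12.7,1.74
patient_8_indium,0.028,0.018,1.44,0.182,2.3,0.161,6.18,10.4,1.68
patient_8_lutetium,0.028,0.020,1.16,0.174,2.5,0.124,6.49,10.9,1.36
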