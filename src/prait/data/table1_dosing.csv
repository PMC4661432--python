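cohort,s1_tf2_mg_m2,s1_tf2_nmol_m2,s1_delay_h,s1_hapten_nmol_m2,s1_activity_MBq,s2_tf2_mg_m2,s2_tf2_nmol_m2,s2_delay_h,s2_hapten_nmol_m2,s2_activity_MBq_m2
I,7,44,48,4.4,185,37.5,240,48,24,1100
II,14,88,48,4.4,185,75,480,48,24,1100
III,14,88,24,4.4,185,75,480,24,24,1100
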