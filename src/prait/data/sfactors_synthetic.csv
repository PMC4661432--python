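source,target,S_mGy_per_MBq_h,ref_mass_kg
wholebody,wholebody,1.164e-03,73.0
wholebody,lungs,8.000e-04,1.0
wholebody,liver,8.000e-04,1.8
wholebody,kidneys,8.000e-04,0.31
wholebody,spleen,8.000e-04,0.18
wholebody,heart,8.000e-04,0.33
wholebody,red_marrow,8.000e-04,1.1
lungs,wholebody,1.100e-03,73.0
lungs,lungs,8.500e-02,1.0
lungs,liver,1.200e-04,1.8
lungs,kidneys,1.200e-04,0.31
lungs,spleen,1.200e-04,0.18
lungs,heart,4.500e-04,0.33
lungs,red_marrow,1.200e-04,1.1
liver,wholebody,1.100e-03,73.0
liver,lungs,1.200e-04,1.0
liver,liver,4.722e-02,1.8
liver,kidneys,4.500e-04,0.31
liver,spleen,4.500e-04,0.18
liver,heart,1.200e-04,0.33
liver,red_marrow,1.200e-04,1.1
kidneys,wholebody,1.100e-03,73.0
kidneys,lungs,1.200e-04,1.0
kidneys,liver,4.500e-04,1.8
kidneys,kidneys,2.742e-01,0.31
kidneys,spleen,4.500e-04,0.18
kidneys,heart,1.200e-04,0.33
kidneys,red_marrow,1.200e-04,1.1
spleen,wholebody,1.100e-03,73.0
spleen,lungs,1.200e-04,1.0
spleen,liver,4.500e-04,1.8
spleen,kidneys,4.500e-04,0.31
spleen,spleen,4.722e-01,0.18
spleen,heart,1.200e-04,0.33
spleen,red_marrow,1.200e-04,1.1
heart,wholebody,1.100e-03,73.0
heart,lungs,4.500e-04,1.0
heart,liver,1.200e-04,1.8
heart,kidneys,1.200e-04,0.31
heart,spleen,1.200e-04,0.18
heart,heart,2.576e-01,0.33
heart,red_marrow,1.200e-04,1.1
red_marrow,wholebody,1.100e-03,73.0
red_marrow,lungs,1.200e-04,1.0
red_marrow,liver,1.200e-04,1.8
red_marrow,kidneys,1.200e-04,0.31
red_marrow,spleen,1.200e-04,0.18
red_marrow,heart,1.200e-04,0.33
red_marrow,red_marrow,7.727e-02,1.1
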