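tissue,kon_per_h,kon_sd,koff_per_h,koff_sd,fraction_L_per_kg,fraction_sd
lung,1.06e-3,0.06e-3,1.17e-2,0.06e-2,3.38e-2,0.19e-2
liver,1.45e-3,0.11e-3,1.14e-2,0.08e-2,2.33e-2,0.21e-2
kidneys,4.35e-3,0.28e-3,2.22e-2,0.08e-2,5.91e-2,0.37e-2
spleen,1.48e-3,0.11e-3,1.30e-2,0.08e-2,2.21e-2,0.19e-2
heart,0.45e-3,0.04e-3,0.94e-2,0.09e-2,3.08e-2,0.21e-2
aorta,0.61e-3,0.05e-3,1.04e-2,0.09e-2,3.66e-2,0.26e-2
tumor,,,,,2.70e-2,0.26e-2
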