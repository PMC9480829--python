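# Model AC with the unadjusted literature values for k0, E_D27, KM_D27 and
# E_CCD8.
model_id: AC
k0: 3.7e-14
kcat_D27A: 68.0
kcat_D27B: 34.0
E_D27: 1.06e-8
E_CCD7: 1.06e-7
E_CCD8: 1.06e-7
kcat_CCD7: 26000.0
kcat_CCD8: 0.18
KM_D27: 2.6e-4
KM_CCD7: 0.0087
KM_CCD8: 0.0092
KM_MAX1: 5.0e-4
Vmax_MAX1: 6.08e-6
Vmax_ABA8HD: 3.8e-9
KM_ABA8HD: 0.016
phi: 0.5
k: 1.0
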