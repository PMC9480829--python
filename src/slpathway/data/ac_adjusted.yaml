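# Model AC, adjusted parameter set.  phi = 0.5 gives the symmetric ABA8HD
# branch split (mirrors omega = 0.5 in model AB).
model_id: AC
k0: 1.0e-8
kcat_D27A: 68.0
kcat_D27B: 34.0
E_D27: 1.06e-7
E_CCD7: 1.06e-7
E_CCD8: 1.06e-6
kcat_CCD7: 26000.0
kcat_CCD8: 0.18
KM_D27: 0.26
KM_CCD7: 0.0087
KM_CCD8: 0.0092
KM_MAX1: 5.0e-4
Vmax_MAX1: 6.08e-6
Vmax_ABA8HD: 3.8e-9
KM_ABA8HD: 0.016
phi: 0.5
k: 1.0
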