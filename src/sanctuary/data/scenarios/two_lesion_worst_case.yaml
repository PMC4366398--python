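# Two metastatic lesions, worst-case drug heterogeneity (D0=0, D1=100).
kind: two_lesion
delta_d: 100.0
v: 1.0e-4
n0: 1.0e+3
n1: 1.0e+8
beta0: 0.05
alpha0: 0.04
beta1: 0.5
alpha1: 0.4
d_mean: 50.0
drug_response: {ic50: 50.0, m: 2.0, rho: 5.0, s: 0.01}
u: 1.0e-9
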