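# Twenty compartments on a ring, five genotypes, Normal-shaped drug profile.
# Census: one sensitive cell in the lowest-concentration compartment.
kind: ring
sigma: 24.7
v: 0.01
topology: ring
m_compartments: 20
n_genotypes: 5
d_mean: 50.0
b0: 0.2
death0: 0.1
drug_response: {ic50: 100.0, m: 2.0, rho: 1.1, s: 0.01}
u: 1.0e-4
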