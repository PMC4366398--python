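# Onion solid tumor: 1e11 cells, 30 concentric shells, two point mutations
# needed for full resistance at the central vessel.
kind: onion
tau_d: 0.5
n_cells: 1.0e+11
m_shells: 30
n_genotypes: 3
radius: 2.3
tau_g: 1.0
tau_c: 1.0
d0: 500.0
b0: 0.5
death0: 0.4
drug_response: {ic50: 50.0, m: 2.0, rho: 5.0, s: 0.01}
u: 1.0e-9
v: 2.0e-4
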