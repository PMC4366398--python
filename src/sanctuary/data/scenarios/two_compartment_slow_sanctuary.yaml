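# Two-compartment minimal model with a slow sanctuary; used for the
# joint resistant-count distribution study.  Single sensitive cell in the
# drug-containing compartment 1.
kind: two_compartment
n_genotypes: 2
birth: [[0.1, 0.38], [0.099, 0.5]]
death: [[0.05, 0.4], [0.05, 0.4]]
mutation: {u: 1.0e-4}
migration: {v: 1.0e-2, topology: pairwise}
census: {"0,1": 1}
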