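# Constrained pathway comparison, slow-migration landscape.
kind: pathway
landscape: {b00: 0.5, d00: 0.4, b10: 0.48, d10: 0.4, b01: 0.39, d01: 0.4, b11: 0.45, d11: 0.4}
mutation: {u: 1.0e-4}
migration: {v: 1.0e-3}
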