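"""Which route wins: migrate-then-mutate, or mutate-then-migrate?

A sanctuary (compartment 0) seeds a high-drug compartment 1.  Resistance
there can arise by sensitive cells migrating first and mutating in situ,
or by mutating in the sanctuary first and migrating after.  The low-rate
theory predicts the mutation-first route wins exactly when the drug's
growth inhibition delta of sensitive cells exceeds s/(1+s), with s the
fitness cost of resistance.
"""

import sanctuary as sc

s, u, v = 0.04, 1e-4, 1e-4
threshold = s / (1 + s)

print(f"cost of resistance s = {s}, theoretical threshold s/(1+s) = {threshold:.5f}\n")
print("delta   T(mutation-migration)   T(migration-mutation)   faster route")
for delta in (0.01, 0.03, threshold, 0.05, 0.10):
    land = sc.PathwayLandscape.equal_death(b00=0.5, d=0.4, s=s, delta=delta, b11=0.45)
    t_mm, t_migmut = sc.compare_pathway_times(land, u=u, v=v)
    faster = "mutation-migration" if t_mm < t_migmut else "migration-mutation"
    print(f"{delta:5.3f}   {t_mm:18.1f}   {t_migmut:19.1f}   {faster}")

delta_star = sc.crossing_delta(s=s, u=u, v=v)
print(
    f"\nNumerically located crossing: delta* = {delta_star:.4f}"
    f" (theory {threshold:.4f})."
    "\nTimes are conditional mean days until a resistant cell occupies the"
    "\ndrug compartment, starting from one sensitive sanctuary cell."
)
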