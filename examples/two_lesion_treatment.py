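"""Treatment outcome for two metastatic lesions sharing a fixed drug budget.

Lesion 0 (1e3 slow-growing cells) and lesion 1 (1e8 fast-growing cells)
receive concentrations D0 = 50 - dD/2 and D1 = 50 + dD/2.  As the
difference dD grows, lesion 0 turns into a drug sanctuary and treatment
flips from near-certain eradication to near-certain failure.
"""

import numpy as np

import sanctuary as sc

mask = sc.ResistantMask(genotype_min=1)

print("dD    D0     escape prob   mean relapse (days)")
for delta_d in (0.0, 40.0, 60.0, 80.0, 100.0):
    model, census = sc.build_two_lesion(sc.TwoLesionScenario(delta_d=delta_d, v=1e-3))
    p = sc.escape_probability(model, census, mask)
    t = sc.mean_time_to_resistance(model, census, mask) if p > 0.05 else np.nan
    print(f"{delta_d:5.0f} {50 - delta_d / 2:5.1f}  {p:12.4g}   {t:10.1f}")

print(
    "\nEscape probability is the chance that a resistant lineage ever"
    "\nestablishes; the relapse time is the conditional mean time until"
    "\nresistant cells are present (reported only when failure is likely)."
    "\nThe sharp flip around dD ~ 50 marks lesion 0 becoming a true"
    "\nsanctuary: beyond it, larger heterogeneity accelerates relapse."
)
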