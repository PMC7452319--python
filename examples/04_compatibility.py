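"""Check chemical-fungus compatibility before mixing the agents.

Colony diameters on pesticide-amended agar plates (5 replicates per
concentration) give the growth inhibition rate; haemocytometer counts of
germinated spores give the germination percentage.  Low inhibition and
high germination mean the chemical is safe to combine with the fungus.
"""

import pandas as pd

from mixtox import summarize_compatibility

rows = []
for rep in range(5):
    rows.append(dict(concentration=0.0, unit="mg/L", replicate=rep,
                     colony_diameter_cm=5.2, germinated=0, observed=0))
for conc, diam, germ in [(0.5, 5.1, 188), (5.0, 4.9, 182), (50.0, 4.4, 160), (500.0, 3.2, 95)]:
    for rep in range(5):
        rows.append(dict(concentration=conc, unit="mg/L", replicate=rep,
                         colony_diameter_cm=diam, germinated=germ // 5, observed=40))

results = summarize_compatibility(pd.DataFrame(rows))
print("conc (mg/L)  inhibition (%)  germination (%)")
for r in results:
    print(f"{r.concentration:>10.1f} {r.inhibition_pct:>14.1f} {r.germination_pct:>16.1f}")

print("\nInhibition below ~20% and germination above ~80% at field-relevant")
print("concentrations indicate the chemical is compatible with the fungus.")
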