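"""Score the interaction of a binary mixture with the co-toxicity coefficient.

Given LC50s for agent A, agent B, and their mixture M at a known weight
ratio, the CTC compares M's observed potency with the dose-additive
(weighted harmonic mean) reference: CTC = 100 means additivity, > 120
synergism, < 80 antagonism.
"""

from mixtox import MixtureRatio, additive_lc50, compute_ctc

lc50_a = 5.76  # mg/L, agent A alone
lc50_b = 20.0  # mg/L, agent B alone (converted to a common potency unit)

print("ratio  additive-LC50  mixture-LC50   CTC     interaction")
for parts, lc50_m in [((9, 1), 7.0), ((1, 1), 4.0), ((1, 4), 2.0)]:
    ratio = MixtureRatio.from_parts(*parts)
    ref = additive_lc50(lc50_a, lc50_b, ratio)
    res = compute_ctc(lc50_a, lc50_b, lc50_m, ratio)
    print(
        f"{parts[0]}:{parts[1]:<4} {ref:>10.2f} {lc50_m:>13.2f} "
        f"{res.ctc:>8.2f}   {res.label}"
    )

print("\nA mixture LC50 below the additive reference means the components")
print("kill more than their weighted potencies predict (CTC > 100);")
print("the ratio with the highest CTC is the optimal formulation.")
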