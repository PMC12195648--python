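"""Potency arithmetic: pIC50 conversion and selectivity indices.

pIC50 = -log10(IC50 in molar) turns micromolar potencies into the
log-scale response modeled by the QSAR pipeline; the selectivity index
SI = GI50(non-tumour) / GI50(tumour) summarises how preferentially a
compound hits cancer cells.
"""

from fieldqsar import pic50_from_ic50, selectivity_index

for ic50 in (86.46, 0.33, 0.015):
    print(f"IC50 {ic50:>7} uM  ->  pIC50 {pic50_from_ic50(ic50):.3f}")

si_k562 = selectivity_index(25.0, 0.30)
si_kcl22 = selectivity_index(25.0, 1.54)
si_censored = selectivity_index(25.0, 0.30, nontumor_censored=True)
print(f"SI (HEK-293T 25 uM / K562 0.30 uM)  = {si_k562.display}")
print(f"SI (HEK-293T 25 uM / KCL22 1.54 uM) = {si_kcl22.display}")
print(f"same ratio, censored non-tumour GI50: {si_censored.display}")

# A large SI (tens) means growth inhibition needs far lower doses in the
# tumour line than in the non-tumour control - the selectivity a lead
# compound should show.
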