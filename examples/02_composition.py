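"""Composition statistics: mol%, saturation categories and carnitine ratios.

Builds a small normalized profile by hand and prints the within-class
mol% shares, the SFA/MUFA/PUFA split, and the C18/C2 energy ratios.
"""

import pandas as pd

from mrmlipid import (
    LipidClass,
    NormalizedProfile,
    carnitine_ratios,
    category_molpct,
    molpct,
    parse_species,
    saturation_ratios,
)

values = pd.DataFrame(
    {
        "s1": [2.0, 6.0, 2.0, 4.0, 1.0, 2.0],
        "s2": [3.0, 5.0, 2.0, 4.0, 1.0, 3.0],
    },
    index=["PC aa C34:0", "PC aa C34:1", "PC aa C36:4",
           "C2", "C16:0", "C18:0"],
)
profile = NormalizedProfile(
    values=values,
    sample_groups={"s1": "control", "s2": "deficient"},
    replicate_counts=values * 0 + 3,
    species_classes={n: parse_species(n).lipid_class for n in values.index},
)

frag = molpct(profile, LipidClass.PC_AA)
print("diacyl-PC mol% per sample (sums to 100 within the class):")
print(frag.species_molpct.round(2))

cat = category_molpct(frag, "saturation")
print("\nsaturation split (mol%):")
print(cat.round(2))
print("\nsaturation ratios (dimensionless):")
print(saturation_ratios(cat).round(3))

carn = carnitine_ratios(profile)
print("\ncarnitine energy ratios (long-chain acyl vs acetyl-carnitine;")
print("an increase suggests impaired fatty-acid turnover in beta-oxidation):")
print(carn.ratios.round(3))
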