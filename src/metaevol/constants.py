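"""Physical constants used in accurate-mass adduct matching.

Monoisotopic mass offsets (Da) added to a neutral metabolite mass M to give
the m/z of the singly charged adduct observed in the indicated ionization
mode.  Values follow standard atomic masses (CODATA / IUPAC 2021) with the
electron mass accounted for in the charged species.
"""

from __future__ import annotations

# Singly charged adducts: offset = m/z - M
PROTON = 1.007276
NH4 = 18.033823          # [M+NH4]+ = M + NH3 + H+ - (electron already folded in)
NA_MINUS_E = 22.989218   # [M+Na]+  = M + Na - e
MINUS_H = -1.007276      # [M-H]-   = M - H+
FORMATE = 44.998201      # [M+HCOO]- = M + formic acid - H+

#: adduct name -> mass offset, keyed by ionization mode
ADDUCTS = {
    "positive": {
        "[M+H]+": PROTON,
        "[M+NH4]+": NH4,
        "[M+Na]+": NA_MINUS_E,
    },
    "negative": {
        "[M-H]-": MINUS_H,
        "[M+FA-H]-": FORMATE,
    },
}

#: canonical tissue vocabulary and composite groupings
TISSUES = ("PFC", "V1", "CBC", "kidney", "muscle")
COMPOSITE_TISSUES = {
    "cortex": ("PFC", "V1"),
    "brain": ("PFC", "V1", "CBC"),
}
TISSUE_CATEGORIES = TISSUES + tuple(COMPOSITE_TISSUES)

SPECIES = ("human", "chimpanzee", "macaque", "mouse")
PRIMATES = ("human", "chimpanzee", "macaque")

#: evolutionary lineage labels and the extant species carrying each lineage
LINEAGES = ("human", "chimp", "macaque_anc", "mouse_anc")
LINEAGE_SPECIES = {
    "human": "human",
    "chimp": "chimpanzee",
    "macaque_anc": "macaque",
    "mouse_anc": "mouse",
}
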