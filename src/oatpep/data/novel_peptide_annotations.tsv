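peptide	solubility	resistant_to_digestion	toxicity	allergenicity
FFG	poor	no	Non-toxin	Non-allergen
IFFFL	poor	no	Non-toxin	Non-allergen
PFL	poor	no	Non-toxin	Non-allergen
WWK	good	no	Non-toxin	33.3%
WCY	poor	no	Non-toxin	33.3%
FPIL	poor	no	Non-toxin	Non-allergen
CPA	poor	yes	Non-toxin	Non-allergen
FLLA	poor	no	Non-toxin	Non-allergen
FEPL	good	no	Non-toxin	Non-allergen
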