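# Nearest-neighbor parameter set "mfold23" (dG37 only; no enthalpies, so
# this set supports 37 C exclusively).  See turner04.txt for the format.
meta set_id mfold23
meta has_enthalpy false

# Watson-Crick / Watson-Crick stacks
stack AU AU  -0.9  NA
stack AU UA  -0.9  NA
stack UA AU  -1.1  NA
stack CG UA  -1.7  NA
stack CG AU  -1.8  NA
stack GC UA  -2.1  NA
stack GC AU  -2.3  NA
stack CG GC  -2.0  NA
stack GC GC  -2.9  NA
stack GC CG  -3.4  NA

# GU wobble stacks
stack AU GU  -0.5  NA
stack AU UG  -0.7  NA
stack CG GU  -1.5  NA
stack CG UG  -1.5  NA
stack GC GU  -1.3  NA
stack GC UG  -1.9  NA
stack UA GU  -0.8  NA
stack UA UG  -0.6  NA
stack GU GU  -0.5  NA
stack GU UG   0.5  NA
stack UG GU   0.3  NA

hairpin 3 4.5
hairpin 4 5.5
hairpin 5 4.9
hairpin 6 5.1
hairpin 7 5.2
hairpin 8 5.5
hairpin 9 5.8

bulge 1 3.9
bulge 2 3.1
bulge 3 3.5
bulge 4 4.2
bulge 5 4.8
bulge 6 5.0

internal 2 4.1
internal 3 5.1
internal 4 4.9
internal 5 5.3
internal 6 5.7

param internal_asym_coef 0.5
param internal_asym_max 3.0

param ml_a 4.6
param ml_b 0.4
param ml_c 0.1

param coax_mismatch_factor 0.5
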