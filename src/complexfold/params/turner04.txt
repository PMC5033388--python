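# Nearest-neighbor parameter set "turner04".
#
# Format (whitespace-separated, '#' comments):
#   meta  <key> <value>
#   stack <outer> <inner> <dG37 kcal/mol> <dH kcal/mol | NA>
#       outer/inner are base pairs written 5'-base then 3'-base of the pair;
#       the doublet is 5'-outer[0] inner[0]-3' over 3'-outer[1] inner[1]-5'.
#       Entries are stored once per symmetry class; lookup applies the
#       reverse-orientation identity stack(o,i) == stack(rev(i), rev(o)).
#   hairpin|bulge|internal <loop length nt> <dG37 kcal/mol>
#   param <name> <value>
#
# dH values enable dG(T) = dH - T*dS with dS = (dH - dG37)/310.15.
# Loop terms are treated as purely entropic: dG(T) = dG37 * T/310.15.
meta set_id turner04
meta has_enthalpy true

# Watson-Crick / Watson-Crick stacks
stack AU AU  -0.93   -6.82
stack AU UA  -1.10   -9.38
stack UA AU  -1.33   -7.69
stack CG UA  -2.08  -10.48
stack CG AU  -2.11  -10.44
stack GC UA  -2.24  -11.40
stack GC AU  -2.35  -12.44
stack CG GC  -2.36  -10.64
stack GC GC  -3.26  -13.39
stack GC CG  -3.42  -14.88

# GU wobble stacks
stack AU GU  -0.55   -3.21
stack AU UG  -1.36   -8.81
stack CG GU  -1.41   -5.61
stack CG UG  -2.11  -12.11
stack GC GU  -1.53   -8.33
stack GC UG  -2.51  -12.59
stack UA GU  -1.00   -6.30
stack UA UG  -0.90   -6.10
stack GU GU  -0.50   -7.00
stack GU UG   0.47   -5.00
stack UG GU   0.30   -3.00

# Loop initiation free energies (dG37); longer loops are extrapolated with
# dG(l) = dG(lmax) + 1.75*R*T*ln(l/lmax).
hairpin 3 5.4
hairpin 4 5.6
hairpin 5 5.7
hairpin 6 5.4
hairpin 7 6.0
hairpin 8 5.5
hairpin 9 6.4

bulge 1 3.8
bulge 2 2.8
bulge 3 3.2
bulge 4 3.6
bulge 5 4.0
bulge 6 4.4

internal 2 1.2
internal 3 1.6
internal 4 1.7
internal 5 1.8
internal 6 2.0

param internal_asym_coef 0.6
param internal_asym_max 3.0

# Multiloop: dG = ml_a + ml_b * (number of closing pairs) + ml_c * (unpaired nt)
param ml_a 9.3
param ml_b -0.9
param ml_c -0.6

# Mismatch-mediated (1-nt gap) coaxial stacks are scaled flush stacks.
param coax_mismatch_factor 0.5
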