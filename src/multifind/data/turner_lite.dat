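# Turner-lite nearest-neighbor free-energy parameters (kcal/mol, 37 C)
#
# A deliberately reduced nearest-neighbor model: helix stacking increments,
# loop-length initiation penalties (hairpin / bulge / internal), a linear
# multibranch-loop model and a terminal AU/GU helix-end penalty.  Dangling
# ends, coaxial stacking and special-case loops are intentionally absent so
# that the minimum-free-energy search, the partition function and structure
# scoring all decompose identically.
#
# Stack entries are read as: pair (i,j) followed by pair (i+1,j-1), i.e.
#   STACK XY WZ e   is the increment for  5'-X W-3'
#                                         3'-Y Z-5'
# The table satisfies the strand-reversal symmetry E(P1,P2) = E(rev P2, rev P1).
#
# Loop tables give the initiation penalty per loop size (unpaired
# nucleotides).  Sizes beyond the largest tabulated entry are extrapolated
# logarithmically: dG(L) = dG(Lmax) + 1.75 * RT * ln(L / Lmax).

TEMPERATURE        310.15
RT                 0.6163
TERMINAL_AU        0.50
MULTIBRANCH_OFFSET 9.3
MULTIBRANCH_HELIX  -0.6
MULTIBRANCH_UNPAIRED 0.0
MIN_HAIRPIN        3
MAX_INTERNAL_LOOP  30

# ---- helix stacking increments -------------------------------------------
STACK AU AU -0.93
STACK AU CG -2.24
STACK AU GC -2.08
STACK AU UA -1.10
STACK AU GU -0.55
STACK AU UG -1.36
STACK UA AU -1.33
STACK UA CG -2.35
STACK UA GC -2.11
STACK UA UA -0.93
STACK UA GU -1.00
STACK UA UG -1.27
STACK CG AU -2.11
STACK CG CG -3.26
STACK CG GC -2.36
STACK CG UA -2.08
STACK CG GU -1.41
STACK CG UG -2.11
STACK GC AU -2.35
STACK GC CG -3.42
STACK GC GC -3.26
STACK GC UA -2.24
STACK GC GU -1.53
STACK GC UG -2.51
STACK GU AU -1.27
STACK GU CG -2.51
STACK GU GC -2.11
STACK GU UA -1.36
STACK GU GU -0.50
STACK GU UG 0.47
STACK UG AU -1.00
STACK UG CG -1.53
STACK UG GC -1.41
STACK UG UA -0.55
STACK UG GU 0.30
STACK UG UG -0.50

# ---- hairpin loop initiation ---------------------------------------------
HAIRPIN 3 5.4
HAIRPIN 4 5.6
HAIRPIN 5 5.7
HAIRPIN 6 5.4
HAIRPIN 7 6.0
HAIRPIN 8 5.5
HAIRPIN 9 6.4

# ---- bulge loop initiation -----------------------------------------------
BULGE 1 3.8
BULGE 2 2.8
BULGE 3 3.2
BULGE 4 3.6
BULGE 5 4.0
BULGE 6 4.4

# ---- internal loop initiation (size = total unpaired, both strands) ------
INTERNAL 2 1.7
INTERNAL 3 1.8
INTERNAL 4 2.0
INTERNAL 5 2.2
INTERNAL 6 2.5
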