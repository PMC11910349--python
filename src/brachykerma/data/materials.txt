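# Bundled tissue materials: elemental mass fractions and nominal densities.
# ICRU-46-style adult reference compositions (body tissues) and ICRU dry air.
# Format: one block per material:
#   material <name> density <g/cm^3>
#   <element symbol> <mass fraction>  (one per line; fractions sum to 1)
# Users may supply their own file with the same layout.

material water density 1.000
H 0.1119
O 0.8881

material air density 0.0012
C 0.000124
N 0.755267
O 0.231781
Ar 0.012827

material lung density 0.26
H 0.103
C 0.105
N 0.031
O 0.749
Na 0.002
P 0.002
S 0.003
Cl 0.003
K 0.002

material adipose density 0.95
H 0.114
C 0.598
N 0.007
O 0.278
Na 0.001
S 0.001
Cl 0.001

material gland density 1.02
H 0.106
C 0.332
N 0.030
O 0.527
Na 0.001
P 0.001
S 0.002
Cl 0.001

material soft_tissue density 1.06
H 0.102
C 0.143
N 0.034
O 0.708
Na 0.002
P 0.003
S 0.003
Cl 0.002
K 0.003

material bone density 1.92
H 0.034
C 0.155
N 0.042
O 0.435
Na 0.001
Mg 0.002
P 0.103
S 0.003
Ca 0.225
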