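# Element-typed Lennard-Jones parameters (Tripos-5.2-style values; Clark,
# Cramer & Van Opdenbosch, J. Comput. Chem. 1989, 10, 982).
# r_star: minimum-energy radius in Angstrom (combined via r_i + r_j),
# epsilon: well depth in kcal/mol (combined via sqrt(eps_i * eps_j)).
element,r_star,epsilon
H,1.50,0.042
C,1.70,0.107
N,1.55,0.095
O,1.52,0.116
S,1.80,0.314
Br,1.85,0.434
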