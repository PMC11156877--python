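# [4+2]-cycloaddition via in-situ cyclic allene: reagent A as in the [2+2]
# case (anhydride or acyl chloride), reagent B a furan, cyclopentadiene or
# pyrrole diene. Each diene family carries three inclusion patterns grading
# steric hindrance at the 2/5 positions (both H, one H, neither H); a block
# qualifies if it matches any of them. Pyrroles must be N-substituted with a
# non-aromatic carbon.
SYNTHON	A_ANHYDRIDE	[#6][CX3D3!R](=O)[O!R][CX3D3!R](=O)[#6]
SYMMETRIC	A_ANHYDRIDE	[*:1]C(=O)OC(=O)[*:2]
TAG	A_ANHYDRIDE	CC42_ANH
SYNTHON	A_ACYL_CHLORIDE	[#6][CX3D3!R](=O)Cl
TAG	A_ACYL_CHLORIDE	CC42_ACL
SYNTHON	B_FURAN	[cX3H1]1o[cX3H1][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1|[cX3H0&$(c!@[#6])]1o[cX3H1][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1|[cX3H0&$(c!@[#6])]1o[cX3H0&$(c!@[#6])][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1
TAG	B_FURAN	CC42_FURAN
SYNTHON	B_CYCLOPENTADIENE	[CX3H1]1=[CX3H0&$(C!@[#6]),CX3H1][CX3H0&$(C!@[#6]),CX3H1]=[CX3H1][CX4H2]1|[CX3H0&$(C!@[#6])]1=[CX3H0&$(C!@[#6]),CX3H1][CX3H0&$(C!@[#6]),CX3H1]=[CX3H1][CX4H2]1|[CX3H0&$(C!@[#6])]1=[CX3H0&$(C!@[#6]),CX3H1][CX3H0&$(C!@[#6]),CX3H1]=[CX3H0&$(C!@[#6])][CX4H2]1
TAG	B_CYCLOPENTADIENE	CC42_CP
SYNTHON	B_PYRROLE	[cX3H1]1n([#6!c])[cX3H1][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1|[cX3H0&$(c!@[#6])]1n([#6!c])[cX3H1][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1|[cX3H0&$(c!@[#6])]1n([#6!c])[cX3H0&$(c!@[#6])][cX3H0&$(c!@[#6]),cX3H1][cX3H0&$(c!@[#6]),cX3H1]1
TAG	B_PYRROLE	CC42_PYR
EXCLUDE	*	[OX2][OX2]
EXCLUDE	*	N=[N+]=[N-]
EXCLUDE	*	[NX2]=C=[OX1]
EXCLUDE	*	[NX2]=C=[SX1]
EXCLUDE	*	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
EXCLUDE	*	[NX2]=[OX1]
EXCLUDE	*	[NX3][F,Cl,Br,I]
EXCLUDE	*	[#6;r3][O,N,S;r3]
EXCLUDE	*	[SX2H1]
EXCLUDE	*	[CX4][Cl,Br,I]
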